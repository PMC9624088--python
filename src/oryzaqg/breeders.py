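"""Response to selection via the multivariate breeder's equation Δz = Gβ.

The predicted per-generation response of each trait is decomposed into a
direct component (its own genetic variance times its selection gradient)
and an indirect component (genetic covariances with the other traits,
each weighted by that trait's gradient).  A trait is flagged as
evolutionarily constrained when direct and indirect components point in
opposite directions and the indirect component exceeds the standard error
of the selection gradient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from oryzaqg.quantgen import GMatrix
from oryzaqg.selection import SelectionGradients


@dataclass
class ResponsePrediction:
    """Per-trait predicted response in SD units per generation.

    ``table`` columns: beta, se, direct, indirect, total, constrained.
    Invariant: direct + indirect == total exactly.
    """

    table: pd.DataFrame
    environment: str = ""
    panel: str = ""

    @property
    def traits(self) -> list[str]:
        return list(self.table.index)


def _coerce_g(G) -> tuple[pd.DataFrame, str, str]:
    if isinstance(G, GMatrix):
        return G.values, G.environment, G.panel
    return G, "", ""


def _coerce_gradients(grads) -> pd.DataFrame:
    if isinstance(grads, SelectionGradients):
        return grads.table
    return grads


def predict_response(G, grads) -> ResponsePrediction:
    """Δz = Gβ with direct/indirect decomposition and constraint flags.

    ``G`` may be a :class:`GMatrix` or a symmetric DataFrame; ``grads`` a
    :class:`SelectionGradients` or a DataFrame with ``beta`` (and
    optionally ``se``) columns.  Traits masked out of G (unmeasured in the
    environment) are dropped from the computation rather than zero-filled.
    """
    g_df, environment, panel = _coerce_g(G)
    gr = _coerce_gradients(grads)
    traits = list(g_df.index)
    missing = [t for t in traits if t not in gr.index]
    if missing:
        raise ValueError(f"gradients missing for G-matrix traits: {missing}")

    Ga = g_df.loc[traits, traits].to_numpy(dtype=float)
    beta = gr.loc[traits, "beta"].to_numpy(dtype=float)
    direct = np.diag(Ga) * beta
    total = Ga @ beta
    indirect = total - direct
    table = pd.DataFrame(
        {
            "beta": beta,
            "se": gr.loc[traits, "se"].to_numpy(dtype=float) if "se" in gr.columns else np.nan,
            "direct": direct,
            "indirect": indirect,
            "total": direct + indirect,
        },
        index=pd.Index(traits, name="trait"),
    )
    pred = ResponsePrediction(table=table, environment=environment, panel=panel)
    return flag_constraints(pred)


def flag_constraints(r: ResponsePrediction) -> ResponsePrediction:
    """Flag traits whose indirect selection opposes and outweighs direct selection.

    A trait is constrained when sign(direct) ≠ sign(indirect) and
    |indirect| > SE(β).  Traits with a zero direct or indirect component
    are never flagged.
    """
    t = r.table
    direct = t["direct"].to_numpy(dtype=float)
    indirect = t["indirect"].to_numpy(dtype=float)
    se = t["se"].to_numpy(dtype=float)
    opposite = np.sign(direct) * np.sign(indirect) < 0
    nonzero = (direct != 0.0) & (indirect != 0.0)
    with np.errstate(invalid="ignore"):
        exceeds = np.abs(indirect) > se
    t = t.copy()
    t["constrained"] = opposite & nonzero & np.where(np.isnan(se), False, exceeds)
    return ResponsePrediction(table=t, environment=r.environment, panel=r.panel)
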