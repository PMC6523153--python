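"""Response-variable preparation: deregression, reliability filter, weights.

The GWAS response for animal i is a deregressed estimated breeding value
(DEBV) y_i whose error variance depends on the reliability r_i^2 of the
underlying EBV.  Records are therefore weighted by

    w_i = (1 - h^2) / { [c + (1 - r_i^2)/r_i^2] * h^2 }

where h^2 is the trait heritability and c the fraction of genetic variance
not captured by markers (default 0.40).  The weight enters the sampler as a
heteroscedastic residual variance sigma_e^2 / w_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_C = 0.40
DEFAULT_MIN_RELIABILITY = 0.10


@dataclass(frozen=True)
class WeightingParams:
    h2: float
    c: float = DEFAULT_C

    def __post_init__(self):
        if not 0.0 < self.h2 < 1.0:
            raise ValueError(f"h2 must lie in (0,1), got {self.h2}")
        if not 0.0 <= self.c < 1.0:
            raise ValueError(f"c must lie in [0,1), got {self.c}")


def compute_weight(reliability, params: WeightingParams, form: str = "ratio"):
    """Per-record weighting factor for heterogeneous DEBV variance.

    ``form="ratio"`` is the standard (Garrick) form above, strictly
    increasing in reliability.  ``form="literal"`` is the product
    (1-h2)*{c+(1-r2)/r2}*h2, kept for comparison with sources that print the
    formula without a division bar.
    """
    r2 = np.asarray(reliability, dtype=float)
    if np.any(r2 <= 0.0):
        raise ValueError("reliability must be > 0 (weight undefined at 0)")
    if np.any(r2 > 1.0):
        raise ValueError("reliability must be <= 1")
    bracket = params.c + (1.0 - r2) / r2
    if form == "ratio":
        w = (1.0 - params.h2) / (bracket * params.h2)
    elif form == "literal":
        w = (1.0 - params.h2) * bracket * params.h2
    else:
        raise ValueError(f"unknown weight form {form!r}")
    if w.ndim == 0:
        return float(w)
    return w


def deregress(ebv, parent_average=None, reliability=1.0):
    """Remove shrinkage (and the parental contribution) from an EBV.

    With a parent average pa: debv = pa + (ebv - pa)/r2; without one the EBV
    is simply expanded by 1/r2.  This is the simple shrinkage-inversion rule;
    users holding properly deregressed proofs skip this step.
    """
    r2 = np.asarray(reliability, dtype=float)
    if np.any(r2 <= 0.0):
        raise ValueError("reliability must be > 0")
    if np.any(r2 > 1.0):
        raise ValueError("reliability must be <= 1")
    ebv = np.asarray(ebv, dtype=float)
    if parent_average is None:
        out = ebv / r2
    else:
        pa = np.asarray(parent_average, dtype=float)
        out = pa + (ebv - pa) / r2
    if out.ndim == 0:
        return float(out)
    return out


def filter_by_reliability(records: pd.DataFrame, min_r2: float = DEFAULT_MIN_RELIABILITY) -> pd.DataFrame:
    """Keep records with reliability >= min_r2 (the boundary is retained)."""
    if not 0.0 <= min_r2 <= 1.0:
        raise ValueError("min_r2 must lie in [0,1]")
    return records.loc[records["reliability"] >= min_r2].copy()


def add_weights(records: pd.DataFrame, h2_by_trait: dict, c: float = DEFAULT_C,
                form: str = "ratio") -> pd.DataFrame:
    """Append a ``weight`` column to a long response table, per trait h2."""
    out = records.copy()
    weights = np.empty(len(out))
    for trait, sub in out.groupby("trait"):
        params = WeightingParams(h2=h2_by_trait[trait], c=c)
        weights[out.index.get_indexer(sub.index)] = compute_weight(
            sub["reliability"].to_numpy(), params, form=form
        )
    out["weight"] = weights
    return out
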