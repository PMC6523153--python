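"""Evidence measures: 1-Mb window variance shares, Bayes factors, classes.

A Bayesian whole-genome regression offers no P-values; instead each marker's
posterior inclusion probability ("model frequency" p) is turned into a Bayes
factor against its prior pi,

    BF = [p/(1-p)] / [(1-pi)/pi],

classified on the Jeffreys-style scale (>3.2 suggestive, >20 strong, >100
decisive).  Because LD spreads a QTL's signal over neighbouring markers, the
genome is also cut into consecutive non-overlapping 1-Mb windows and each
window's share of the total genomic variance is reported (GV%), with windows
explaining more than 1% flagged informative.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

WINDOW_BP = 1_000_000
GV_THRESHOLD_PCT = 1.0
BF_SUGGESTIVE = 3.2
BF_STRONG = 20.0
BF_DECISIVE = 100.0
EVIDENCE_LEVELS = ("none", "suggestive", "strong", "decisive")


def assign_window(chrom, pos_bp) -> str:
    """Label "chrom_Mb" of the half-open 1-Mb window containing pos_bp."""
    pos = np.asarray(pos_bp)
    if np.any(pos < 0):
        raise ValueError("negative genomic position")
    idx = pos // WINDOW_BP
    if np.ndim(pos_bp) == 0:
        return f"{chrom}_{int(idx)}"
    return np.char.add(np.char.add(np.asarray(chrom, dtype=str), "_"), idx.astype(str))


def bayes_factor(model_freq, pi: float):
    """Posterior odds of inclusion over prior odds; p=1 maps to +inf."""
    if not 0.0 < pi < 1.0:
        raise ValueError(f"pi must lie in (0,1), got {pi}")
    p = np.asarray(model_freq, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("model frequency must lie in [0,1]")
    prior_odds = (1.0 - pi) / pi
    with np.errstate(divide="ignore"):
        bf = np.where(p >= 1.0, np.inf, p / (1.0 - np.where(p >= 1.0, 0.5, p)) / prior_odds)
    if bf.ndim == 0:
        return float(bf)
    return bf


def classify_evidence(bf):
    """Jeffreys-style class for a Bayes factor (strict '>' at each boundary)."""
    b = np.asarray(bf, dtype=float)
    if np.any(b < 0):
        raise ValueError("Bayes factor must be non-negative")
    out = np.full(b.shape, "none", dtype=object)
    out[b > BF_SUGGESTIVE] = "suggestive"
    out[b > BF_STRONG] = "strong"
    out[b > BF_DECISIVE] = "decisive"
    if out.ndim == 0:
        return str(out[()])
    return out


def snp_significance(marker_ids, model_freq, pi: float) -> pd.DataFrame:
    bf = bayes_factor(model_freq, pi)
    return pd.DataFrame(
        {
            "marker_id": list(marker_ids),
            "model_freq": np.asarray(model_freq, dtype=float),
            "bayes_factor": bf,
            "evidence_class": classify_evidence(bf),
        }
    )


def window_variance_table(saved_u: np.ndarray, dosages: np.ndarray,
                          marker_map: pd.DataFrame) -> pd.DataFrame:
    """Posterior-mean per-window shares of total genomic variance.

    For every saved effect sample u the genome-wide values g = Zc u are
    decomposed over the 1-Mb windows of the map: share_w = var(Zc_w u_w) /
    var(g) across animals.  Shares are averaged over samples and reported as
    percentages.  Samples with zero total genomic variance are skipped.
    Columns: window_id, chrom, window_mb, gv_pct, n_markers, marker_ids.
    """
    S, m = saved_u.shape
    if S == 0:
        raise ValueError("no saved samples")
    if len(marker_map) != m:
        raise ValueError("marker map and effect samples disagree in length")
    Z = np.asarray(dosages, dtype=float)
    Zc = Z - Z.mean(axis=0)
    win = assign_window(marker_map["chrom"].to_numpy(), marker_map["pos_bp"].to_numpy())
    codes, labels = pd.factorize(win)
    n_win = len(labels)
    shares = np.zeros(n_win)
    used = 0
    for s in range(S):
        u = saved_u[s]
        nz = np.flatnonzero(u)
        if nz.size == 0:
            warnings.warn("sample with zero total genomic variance skipped", stacklevel=2)
            continue
        g_tot = np.zeros(Zc.shape[0])
        per_win = {}
        for w in np.unique(codes[nz]):
            idx = nz[codes[nz] == w]
            gw = Zc[:, idx] @ u[idx]
            per_win[w] = gw.var()
            g_tot += gw
        tot = g_tot.var()
        if tot <= 0:
            warnings.warn("sample with zero total genomic variance skipped", stacklevel=2)
            continue
        for w, vw in per_win.items():
            shares[w] += vw / tot
        used += 1
    if used == 0:
        raise ValueError("all samples had zero genomic variance")
    shares = 100.0 * shares / used
    rows = []
    for w, label in enumerate(labels):
        members = marker_map.loc[codes == w, "marker_id"]
        chrom, mb = str(label).rsplit("_", 1)
        rows.append((label, chrom, int(mb), shares[w], len(members), ",".join(members)))
    out = pd.DataFrame(
        rows, columns=["window_id", "chrom", "window_mb", "gv_pct", "n_markers", "marker_ids"]
    )
    return out.sort_values("gv_pct", ascending=False).reset_index(drop=True)


def informative_regions(windows: pd.DataFrame, snps: pd.DataFrame,
                        marker_map: pd.DataFrame, effects=None, trait: str = "",
                        gv_threshold: float = GV_THRESHOLD_PCT,
                        bf_threshold: float = BF_STRONG) -> pd.DataFrame:
    """Report-shaped rows for informative windows and their top markers.

    A window is reported when its GV% exceeds ``gv_threshold`` OR it contains
    a marker whose Bayes factor exceeds ``bf_threshold``.  Within a reported
    window every marker over ``bf_threshold`` is listed; if none is, the
    window's highest-BF marker is listed.
    """
    snp = snps.merge(marker_map, on="marker_id")
    snp["window_id"] = assign_window(snp["chrom"].to_numpy(), snp["pos_bp"].to_numpy())
    if effects is not None:
        eff = pd.Series(np.asarray(effects, dtype=float), index=marker_map["marker_id"].to_numpy())
        snp["effect"] = eff.reindex(snp["marker_id"]).to_numpy()
    else:
        snp["effect"] = np.nan
    rows = []
    for _, wrow in windows.iterrows():
        members = snp[snp["window_id"] == wrow["window_id"]]
        if members.empty:
            continue
        max_bf = members["bayes_factor"].max()
        if not (wrow["gv_pct"] > gv_threshold or max_bf > bf_threshold):
            continue
        listed = members[members["bayes_factor"] > bf_threshold]
        if listed.empty:
            listed = members.loc[[members["bayes_factor"].idxmax()]]
        for _, srow in listed.sort_values("bayes_factor", ascending=False).iterrows():
            rows.append(
                (
                    trait,
                    wrow["window_id"],
                    wrow["gv_pct"],
                    srow["marker_id"],
                    srow["pos_bp"],
                    srow["effect"],
                    srow["bayes_factor"],
                )
            )
    return pd.DataFrame(
        rows,
        columns=["trait", "window_id", "gv_pct", "marker_id", "pos_bp", "effect", "bayes_factor"],
    )
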