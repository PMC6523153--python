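"""Transcription-factor target prediction over promoter sequences.

Network genes are matched against a TF list; each TF with a position weight
matrix has its motif scanned (FIMO-style) over the 2000-bp upstream flank of
every network gene: log2 odds scores against a background model, exact
p-values by dynamic programming over integer-discretized scores, hits called
at p <= 0.001, and a gene is a predicted target if its promoter has at least
one hit.  Finally the trio of TFs whose target sets jointly cover the most
genes is selected by exhaustive search.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .simulate import BASES, PWM

UNIFORM_BG = np.full(4, 0.25)
P_MAX_DEFAULT = 1e-3
SCORE_GRANULARITY = 1e-3

_CODE = {b: i for i, b in enumerate(BASES)}


@dataclass
class TFModule:
    """Predicted regulon of one TF: target gene -> (best score, p-value)."""

    tf: str
    targets: dict

    @property
    def target_set(self) -> frozenset:
        return frozenset(self.targets)


def match_tfs(network_genes, tf_list) -> list:
    """Network gene ids found in the TF list (case-insensitive, deduplicated)."""
    if not tf_list:
        raise ValueError("TF list is empty")
    tfset = {str(t).upper() for t in tf_list}
    seen = set()
    out = []
    for g in network_genes:
        key = str(g).upper()
        if key in tfset and key not in seen:
            seen.add(key)
            out.append(g)
    return out


def log_odds(pwm: PWM, background=None) -> np.ndarray:
    """log2 odds score matrix with the PWM's pseudocount, renormalized.

    score[i, b] = log2(p'[i, b] / background[b]) with
    p' = (p + pseudocount) / (1 + 4*pseudocount).
    """
    bg = UNIFORM_BG if background is None else np.asarray(background, dtype=float)
    if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be 4 frequencies summing to 1")
    if np.any(bg <= 0):
        raise ValueError("background frequencies must be positive")
    p = (pwm.matrix + pwm.pseudocount) / (1.0 + 4.0 * pwm.pseudocount)
    return np.log2(p / bg[None, :])


def _int_scores(score_matrix: np.ndarray) -> np.ndarray:
    """Scores discretized to integer multiples of SCORE_GRANULARITY."""
    return np.rint(np.asarray(score_matrix, dtype=float) / SCORE_GRANULARITY).astype(np.int64)


def score_distribution(score_matrix: np.ndarray, background=None):
    """Exact null distribution of the motif score on random background sequence.

    Returns (offset, probs): probs[k] = P(integer score == offset + k) under
    independent background draws per position, computed by DP convolution on
    the discretized score grid.
    """
    bg = UNIFORM_BG if background is None else np.asarray(background, dtype=float)
    S = _int_scores(score_matrix)
    lo = int(S.min(axis=1).sum())
    hi = int(S.max(axis=1).sum())
    probs = np.zeros(hi - lo + 1)
    # DP over positions; offset tracked implicitly via running minimum
    cur = np.array([1.0])
    cur_lo = 0
    for i in range(S.shape[0]):
        row = S[i]
        rlo, rhi = int(row.min()), int(row.max())
        nxt = np.zeros(len(cur) + rhi - rlo)
        for b in range(4):
            shift = int(row[b]) - rlo
            nxt[shift: shift + len(cur)] += bg[b] * cur
        cur = nxt
        cur_lo += rlo
    probs[cur_lo - lo: cur_lo - lo + len(cur)] = cur
    return lo, probs


def pwm_pvalue(score_matrix: np.ndarray, threshold: float, background=None) -> float:
    """Exact P(motif score >= threshold) for a random background window."""
    lo, probs = score_distribution(score_matrix, background)
    t = int(np.ceil(round(threshold / SCORE_GRANULARITY, 6)))
    if t <= lo:
        return 1.0
    if t > lo + len(probs) - 1:
        return 0.0
    return float(probs[t - lo:].sum())


def _survival(score_matrix: np.ndarray, background=None):
    lo, probs = score_distribution(score_matrix, background)
    surv = np.cumsum(probs[::-1])[::-1]
    return lo, surv


def _encode(sequence: str) -> np.ndarray:
    return np.frombuffer(
        sequence.upper().encode("ascii").translate(_TRANSLATE), dtype=np.uint8
    ).astype(np.int64)


_TRANSLATE = bytes(
    _CODE.get(chr(c), 4) if chr(c) in "ACGT" else 4 for c in range(256)
)


def scan_promoter(score_matrix: np.ndarray, sequence: str,
                  p_max: float = P_MAX_DEFAULT, background=None) -> list:
    """Forward-strand motif scan; hits as (1-based start, score, p-value).

    Windows containing any non-ACGT character are skipped.  Scoring and
    p-values share the same discretized grid, so a hit is exactly a window
    whose integer score has survival probability <= p_max.
    """
    S = _int_scores(score_matrix)
    L = S.shape[0]
    enc = _encode(sequence)
    if len(enc) < L:
        return []
    lo, surv = _survival(score_matrix, background)
    valid = enc < 4
    enc_safe = np.where(valid, enc, 0)
    windows = np.lib.stride_tricks.sliding_window_view(enc_safe, L)
    scores = S[np.arange(L)[None, :], windows].sum(axis=1)
    ok = np.lib.stride_tricks.sliding_window_view(valid, L).all(axis=1)
    hits = []
    for pos in np.flatnonzero(ok):
        s = int(scores[pos])
        p = float(surv[s - lo]) if s >= lo else 1.0
        if s - lo >= len(surv):
            p = 0.0
        if p <= p_max:
            hits.append((int(pos) + 1, s * SCORE_GRANULARITY, p))
    return hits


def assign_targets(tfs, pwms: dict, promoters: dict,
                   p_max: float = P_MAX_DEFAULT, background=None) -> dict:
    """Predicted target genes per TF: any promoter with >=1 hit at p <= p_max.

    TFs without a PWM are dropped with a warning (in real studies motif
    databases cover only part of the TF list); genes without a promoter
    sequence are skipped likewise.
    """
    modules = {}
    for tf in tfs:
        pwm = pwms.get(tf)
        if pwm is None:
            warnings.warn(f"TF {tf} has no motif information; dropped", stacklevel=2)
            continue
        S = log_odds(pwm, background)
        targets = {}
        for gene, seq in promoters.items():
            hits = scan_promoter(S, seq, p_max=p_max, background=background)
            if hits:
                best = max(hits, key=lambda h: h[1])
                targets[gene] = (best[1], best[2])
        modules[tf] = TFModule(tf, targets)
    return modules


def select_top_trio(modules: dict):
    """Exhaustive maximum-coverage search over all TF 3-subsets.

    Returns (trio ids sorted, covered gene count).  Ties broken
    lexicographically by the sorted TF id triple.
    """
    if len(modules) < 3:
        raise ValueError("need at least 3 TF modules for trio selection")
    best = None
    for trio in combinations(sorted(modules), 3):
        cov = len(set().union(*(modules[t].target_set for t in trio)))
        if best is None or cov > best[1]:
            best = (trio, cov)
    return best
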