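"""Copy-number profiling from probe-level log2-ratio tracks.

Segmentation is CBS-style recursive binary splitting: within a segment the
candidate breakpoint maximizes the two-sample t-statistic between left and
right probes, and the split is accepted when a seeded permutation test on the
max-t statistic gives p < alpha. Gain/loss thresholds are derived from normal
reference segment means as median +/- k * 1.4826 * MAD. Coordinates are
0-based half-open, BED-compatible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from svzm.catstats import fisher_exact
from svzm.util import two_classes

log = logging.getLogger(__name__)


@dataclass
class CNVSegment:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # half-open exclusive
    mean_log2ratio: float
    n_probes: int
    state: str = "neutral"  # loss | neutral | gain


def _max_t_split(v: np.ndarray, min_probes: int):
    """Best split index (left length) maximizing |two-sample t|; returns
    (index, t) or (None, 0) when no admissible split exists."""
    n = v.size
    if n < 2 * min_probes:
        return None, 0.0
    cs = np.cumsum(v)
    css = np.cumsum(v**2)
    ks = np.arange(min_probes, n - min_probes + 1)
    n1 = ks.astype(float)
    n2 = n - n1
    s1 = cs[ks - 1]
    s2 = cs[-1] - s1
    m1, m2 = s1 / n1, s2 / n2
    ss1 = css[ks - 1] - n1 * m1**2
    ss2 = (css[-1] - css[ks - 1]) - n2 * m2**2
    dof = n - 2
    pooled = np.maximum((ss1 + ss2) / dof, 1e-12)
    t = np.abs(m1 - m2) / np.sqrt(pooled * (1 / n1 + 1 / n2))
    i = int(np.argmax(t))
    return int(ks[i]), float(t[i])


def _segment_values(
    v: np.ndarray, min_probes: int, alpha_split: float, n_perm: int, rng: np.random.Generator
):
    """Recursive binary segmentation of one value vector; yields (start, end)
    probe-index slices."""
    k, t_obs = _max_t_split(v, min_probes)
    if k is None or t_obs == 0.0:
        return [(0, v.size)]
    exceed = 0
    for _ in range(n_perm):
        _, t_perm = _max_t_split(rng.permutation(v), min_probes)
        if t_perm >= t_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    if p >= alpha_split:
        return [(0, v.size)]
    left = _segment_values(v[:k], min_probes, alpha_split, n_perm, rng)
    right = _segment_values(v[k:], min_probes, alpha_split, n_perm, rng)
    return left + [(a + k, b + k) for a, b in right]


def segment_track(
    track: pd.DataFrame,
    sample: str,
    min_probes: int = 5,
    alpha_split: float = 0.01,
    n_perm: int = 199,
    seed: int = 0,
) -> list:
    """Segment one sample's probe log2-ratio track.

    ``track`` must hold ``chrom``, ``pos`` (sorted within chromosome) and one
    column per sample. Segmentation never crosses a chromosome boundary.
    """
    rng = np.random.default_rng(seed)
    segments = []
    for chrom, sub in track.groupby("chrom", sort=False):
        pos = sub["pos"].values
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"probes on {chrom} are not position-sorted")
        v = sub[sample].values.astype(float)
        for a, b in _segment_values(v, min_probes, alpha_split, n_perm, rng):
            segments.append(
                CNVSegment(
                    chrom=str(chrom),
                    start=int(pos[a]),
                    end=int(pos[b - 1]) + 1,
                    mean_log2ratio=float(v[a:b].mean()),
                    n_probes=int(b - a),
                )
            )
    return segments


def auto_thresholds(reference_means, k: float = 2.5) -> dict:
    """Gain/loss cutoffs from normal-reference segment means:
    median +/- k * 1.4826 * MAD. Raises on zero MAD."""
    v = np.asarray(reference_means, dtype=float)
    if v.size < 20:
        raise ValueError("need >= 20 reference segment means")
    med = float(np.median(v))
    mad = float(np.median(np.abs(v - med))) * 1.4826
    if mad == 0:
        raise ValueError("reference MAD is zero; consider a k-quantile fallback")
    return {"loss_cut": med - k * mad, "gain_cut": med + k * mad}


def call_states(segments: list, thresholds: dict) -> list:
    """Assign loss/neutral/gain to each segment by its mean log2-ratio."""
    out = []
    for s in segments:
        state = "neutral"
        if s.mean_log2ratio < thresholds["loss_cut"]:
            state = "loss"
        elif s.mean_log2ratio > thresholds["gain_cut"]:
            state = "gain"
        out.append(
            CNVSegment(s.chrom, s.start, s.end, s.mean_log2ratio, s.n_probes, state)
        )
    return out


def make_bins(track: pd.DataFrame, width: int = 5_000_000) -> pd.DataFrame:
    """Fixed-width genomic bins covering the probe track (0-based half-open).

    Bins whose midpoint falls outside the probe extent are dropped so every
    emitted bin can be assigned a segment state."""
    rows = []
    for chrom, sub in track.groupby("chrom", sort=False):
        lo, hi = int(sub["pos"].min()), int(sub["pos"].max()) + 1
        start = lo - lo % width
        while start < hi:
            if lo <= start + width / 2 < hi:
                rows.append((str(chrom), start, start + width))
            start += width
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _bin_state(segments: list, chrom: str, mid: float) -> str:
    for s in segments:
        if s.chrom == chrom and s.start <= mid < s.end:
            return s.state
    return "neutral"  # uncovered bins are treated as neutral (flagged upstream)


def group_cnv_comparison(
    segments_by_sample: dict, labels: pd.Series, bins: pd.DataFrame
) -> pd.DataFrame:
    """Per-bin altered-vs-not x class Fisher test.

    Each sample's state in a bin is taken from the segment covering the bin
    midpoint (neutral when uncovered). Returns per-bin alteration frequencies
    in each class and the Fisher p.
    """
    labels, classes = two_classes(labels)
    pos_ids = [s for s in segments_by_sample if labels[s] == classes[0]]
    neg_ids = [s for s in segments_by_sample if labels[s] == classes[1]]
    rows = []
    for _, b in bins.iterrows():
        mid = (b["start"] + b["end"]) / 2
        alt_pos = sum(
            _bin_state(segments_by_sample[s], b["chrom"], mid) != "neutral" for s in pos_ids
        )
        alt_neg = sum(
            _bin_state(segments_by_sample[s], b["chrom"], mid) != "neutral" for s in neg_ids
        )
        table = [
            [alt_pos, alt_neg],
            [len(pos_ids) - alt_pos, len(neg_ids) - alt_neg],
        ]
        rows.append(
            {
                "chrom": b["chrom"],
                "start": int(b["start"]),
                "end": int(b["end"]),
                "freq_pos": alt_pos / max(len(pos_ids), 1),
                "freq_neg": alt_neg / max(len(neg_ids), 1),
                "fisher_p": fisher_exact(table),
            }
        )
    return pd.DataFrame(rows)


def segments_to_frame(segments_by_sample: dict) -> pd.DataFrame:
    """BED-like long table (chrom, start, end, sample, mean_log2ratio, n_probes, state)."""
    rows = []
    for sid, segs in segments_by_sample.items():
        for s in segs:
            rows.append(
                {
                    "chrom": s.chrom,
                    "start": s.start,
                    "end": s.end,
                    "sample": sid,
                    "mean_log2ratio": s.mean_log2ratio,
                    "n_probes": s.n_probes,
                    "state": s.state,
                }
            )
    return pd.DataFrame(rows)
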