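"""Methylation-array preprocessing: probe filtering, beta/M conversion, MAD selection.

Beta values (methylated fraction, in (0,1)) are the on-disk representation;
M-values ``log2(beta/(1-beta))`` are used for statistics. Probe selection for
unsupervised work keeps the probes with the highest median absolute deviation
(MAD) of beta across samples, computed without the 1.4826 consistency constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: clipping bound applied to beta at load time so M-values stay finite
BETA_CLIP = 1e-3

ANNOTATION_FLAGS = ("sex_chrom", "snp_overlap", "repetitive")


@dataclass
class MethylationMatrix:
    """CpG x sample beta-value matrix with per-probe annotation.

    Parameters
    ----------
    beta : pandas.DataFrame
        Probes (rows, indexed by probe id) x samples (columns), values in (0,1).
    annotation : pandas.DataFrame
        Indexed by probe id; columns ``chrom``, ``pos`` (0-based), ``gene``
        (symbol or empty string) and the boolean exclusion flags
        ``sex_chrom``, ``snp_overlap``, ``repetitive``.
    """

    beta: pd.DataFrame
    annotation: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        if self.beta.index.has_duplicates:
            raise ValueError("duplicate probe ids")
        if self.beta.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.annotation is None:
            self.annotation = pd.DataFrame(
                {
                    "chrom": "chrUn",
                    "pos": 0,
                    "gene": "",
                    "sex_chrom": False,
                    "snp_overlap": False,
                    "repetitive": False,
                },
                index=self.beta.index,
            )
        missing = self.beta.index.difference(self.annotation.index)
        if len(missing):
            raise ValueError(f"annotation missing for {len(missing)} probes")
        self.annotation = self.annotation.loc[self.beta.index]
        lo, hi = self.beta.values.min(), self.beta.values.max()
        if lo <= 0.0 or hi >= 1.0:
            log.info("clipping beta values into [%g, %g]", BETA_CLIP, 1 - BETA_CLIP)
            self.beta = self.beta.clip(BETA_CLIP, 1 - BETA_CLIP)

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def m_values(self) -> pd.DataFrame:
        """M-value representation, ``log2(beta/(1-beta))``."""
        return pd.DataFrame(
            beta_to_m(self.beta.values), index=self.beta.index, columns=self.beta.columns
        )

    def subset_probes(self, probe_ids) -> "MethylationMatrix":
        probe_ids = pd.Index(probe_ids)
        missing = probe_ids.difference(self.beta.index)
        if len(missing):
            raise KeyError(f"unknown probes: {list(missing[:5])}")
        return MethylationMatrix(self.beta.loc[probe_ids], self.annotation.loc[probe_ids])

    def subset_samples(self, sample_ids) -> "MethylationMatrix":
        return MethylationMatrix(self.beta[list(sample_ids)], self.annotation)


def beta_to_m(beta):
    """Convert beta values in (0,1) to M-values, ``M = log2(beta/(1-beta))``.

    Strictly increasing; M=0 at beta=0.5. Raises ``ValueError`` outside (0,1).
    """
    b = np.asarray(beta, dtype=float)
    if np.any(b <= 0.0) or np.any(b >= 1.0):
        raise ValueError("beta values must lie strictly inside (0, 1)")
    return np.log2(b / (1.0 - b))


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: ``beta = 2^M / (1 + 2^M)``."""
    m = np.asarray(m, dtype=float)
    # logistic form is stable for large |M|
    return 1.0 / (1.0 + np.exp2(-m))


def filter_probes(m: MethylationMatrix) -> MethylationMatrix:
    """Drop probes on chromosomes X/Y, overlapping SNPs, or in repetitive sequence.

    Keeps exactly the probes with all three exclusion flags false, preserving
    order. Raises if no probes remain.
    """
    ann = m.annotation
    for flag in ANNOTATION_FLAGS:
        if flag not in ann.columns:
            raise ValueError(f"annotation lacks required flag column '{flag}'")
    keep = ~(ann[list(ANNOTATION_FLAGS)].astype(bool).any(axis=1))
    if not keep.any():
        raise ValueError("no probes remain after exclusion-flag filtering")
    return m.subset_probes(m.probe_ids[keep.values])


def mad(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Raw median absolute deviation (no consistency constant)."""
    med = np.median(values, axis=axis, keepdims=True)
    return np.median(np.abs(values - med), axis=axis)


def top_mad_probes(m: MethylationMatrix, k: int) -> MethylationMatrix:
    """Keep the ``k`` probes with the largest MAD of beta across samples.

    Ties are broken by probe id (lexicographic), making the selection stable.
    """
    if k > m.n_probes:
        raise ValueError(f"k={k} exceeds available probes ({m.n_probes})")
    scores = pd.Series(mad(m.beta.values, axis=1), index=m.probe_ids)
    order = scores.sort_values(ascending=False, kind="stable")
    # stable sort on -score with secondary lexicographic key
    tmp = pd.DataFrame({"score": -scores, "pid": scores.index.astype(str)})
    order = tmp.sort_values(["score", "pid"], kind="stable").index
    return m.subset_probes(order[:k])


def normalize(m: MethylationMatrix, method: str = "none") -> MethylationMatrix:
    """Normalization hook. Only ``"none"`` is provided: inputs are expected to be
    normalized upstream (raw-intensity normalization needs idat-level data,
    which this package does not consume)."""
    if method != "none":
        raise ValueError(f"unknown normalization method '{method}'")
    return m


# ---------------------------------------------------------------------------
# TSV I/O

def read_methylation_tsv(beta_path, annotation_path=None) -> MethylationMatrix:
    """Read a probe x sample beta TSV (index column = probe id) and optional
    annotation TSV (probe_id, chrom, pos, gene, sex_chrom, snp_overlap, repetitive)."""
    beta = pd.read_csv(beta_path, sep="\t", index_col=0)
    ann = None
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, sep="\t", index_col=0)
        for flag in ANNOTATION_FLAGS:
            ann[flag] = ann[flag].astype(bool)
        ann["gene"] = ann.get("gene", pd.Series("", index=ann.index)).fillna("")
    return MethylationMatrix(beta, ann)


def write_methylation_tsv(m: MethylationMatrix, beta_path, annotation_path=None) -> None:
    m.beta.to_csv(beta_path, sep="\t", index_label="probe_id")
    if annotation_path is not None:
        m.annotation.to_csv(annotation_path, sep="\t", index_label="probe_id")
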