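"""Synthetic glioblastoma cohort generator.

Emulates the data layers of a two-cohort SVZ-methylome study: a 450K-style
beta-value matrix with a minority of planted differentially methylated CpGs
(predominantly hypomethylated in the SVZM+ class), class-dependent Weibull
survival, expression counts negatively coupled to promoter/body methylation,
arm-level copy-number events, per-gene class-dependent mutations observed
through several noisy calling pipelines, and imperfect MRI raters.

All randomness flows from a single integer seed through named
``numpy.random.SeedSequence`` sub-streams, one per data layer, so the bundle
is byte-identical for a fixed configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from svzm.preprocess import MethylationMatrix, beta_to_m

POS = "SVZ+"
NEG = "SVZ-"

VARIANT_CLASSES = (
    "missense",
    "nonsense",
    "frameshift_ins",
    "frameshift_del",
    "inframe_del",
    "splice_region",
    "splice_site",
    "silent",
    "other",
)

# default non-silent class mix, identical in both groups
_DEFAULT_CLASS_PROBS = {
    "missense": 0.55,
    "nonsense": 0.12,
    "frameshift_ins": 0.08,
    "frameshift_del": 0.08,
    "inframe_del": 0.05,
    "splice_region": 0.05,
    "splice_site": 0.04,
    "other": 0.03,
}


def _default_mutation_rates() -> dict:
    """Per-gene (rate in SVZM+, rate in SVZM-) truth mutation probabilities.

    Background genes mutate equally; a few genes are enriched in one class and
    two are class-exclusive, mirroring the structure the enrichment stage is
    meant to detect.
    """
    rates = {f"GENE{i:03d}": (0.10, 0.10) for i in range(1, 16)}
    rates["ENR_POS1"] = (0.40, 0.05)
    rates["ENR_NEG1"] = (0.05, 0.40)
    rates["ENR_NEG2"] = (0.05, 0.35)
    rates["EXCL_POS1"] = (0.15, 0.0)
    rates["EXCL_NEG1"] = (0.0, 0.15)
    return rates


@dataclass
class SimulationConfig:
    """Study-design parameters for :func:`generate_cohort`.

    Defaults reproduce the training-cohort design: 24 SVZM+ vs 30 SVZM-
    samples, 10,000 CpGs with 200 planted differential probes of which 98%
    are hypomethylated in SVZM+, a planted log hazard ratio of 0.91
    (HR ~2.5) on a Weibull baseline with median survival ~15 months, and
    four mutation-calling pipelines at 0.9 sensitivity.
    """

    n_pos: int = 24
    n_neg: int = 30
    n_probes: int = 10_000
    n_dmp: int = 200
    frac_hypo: float = 0.98
    effect_delta: float = 0.25  # mean beta-shift of planted DMPs
    beta_dispersion: float = 50.0  # beta-distribution concentration
    log_hr: float = 0.91
    weibull_shape: float = 1.4
    weibull_scale: float = 20.0  # months
    censor_rate: float = 0.3
    n_genes: int = 200
    n_coupled: int = 50
    coupling_rho: float = -0.7
    nb_dispersion: float = 0.1  # NB2 alpha
    mean_counts: float = 500.0
    cnv_events: list = field(
        default_factory=lambda: [
            ("chr10", "loss", NEG, 0.7),
            ("chr19", "gain", NEG, 0.7),
        ]
    )
    cnv_probes_per_chrom: int = 120
    cnv_chroms: tuple = ("chr1", "chr10", "chr19")
    cnv_noise_sd: float = 0.1
    cnv_loss_shift: float = -0.5
    cnv_gain_shift: float = 0.4
    n_normal: int = 20
    n_pipelines: int = 4
    pipeline_sensitivity: float = 0.9
    pipeline_false_rate: float = 0.01
    mutation_rates: dict = field(default_factory=_default_mutation_rates)
    variant_class_probs: dict | None = None  # optional per-group class mixes
    silent_frac: float = 0.3
    n_raters: int = 3
    rater_error: float = 0.1
    mri_error: float = 0.0  # training cohorts select consensus-clear cases
    seed: int = 0
    # optional overrides tying a validation cohort to a training cohort's
    # planted probe structure (same DMP positions and shift directions)
    dmp_indices: list | None = None
    dmp_hypo: list | None = None

    def validate(self) -> None:
        for name in ("n_pos", "n_neg", "n_probes", "n_genes", "n_pipelines", "n_raters"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field '{name}' must be > 0")
        for name in ("frac_hypo", "censor_rate", "rater_error", "mri_error",
                     "silent_frac", "pipeline_sensitivity", "pipeline_false_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"config field '{name}' must lie in [0, 1]")
        if not 0 <= self.n_dmp <= self.n_probes:
            raise ValueError("config field 'n_dmp' must lie in [0, n_probes]")
        if not 0 <= self.n_coupled <= self.n_genes:
            raise ValueError("config field 'n_coupled' must lie in [0, n_genes]")
        if not 0.0 <= self.effect_delta < 0.5:
            raise ValueError("config field 'effect_delta' must keep beta means in (0,1)")
        if self.beta_dispersion <= 0:
            raise ValueError("config field 'beta_dispersion' must be > 0")
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise ValueError("config field 'weibull_shape'/'weibull_scale' must be > 0")


@dataclass
class CohortBundle:
    """All simulated data layers, sharing one set of sample identifiers."""

    methylation: MethylationMatrix
    samples: pd.DataFrame  # sample sheet
    expression: pd.DataFrame  # gene x sample integer counts
    gene_cpg_map: pd.DataFrame  # columns: cpg_id, gene
    cnv_input: pd.DataFrame  # chrom, pos + one column per tumor sample
    cnv_reference: pd.DataFrame  # chrom, pos + one column per normal sample
    mutations: pd.DataFrame  # sample_id, gene, pipeline, variant_class, silent
    raters: pd.DataFrame  # sample_id x rater columns
    truth: dict

    def __post_init__(self) -> None:
        sids = list(self.samples["sample_id"])
        assert list(self.methylation.sample_ids) == sids
        assert list(self.expression.columns) == sids


def beta_shift_for_m_shift(m_shift: float, base_beta: float = 0.5) -> float:
    """Beta-scale group difference that corresponds to a symmetric M-value
    shift of ``m_shift`` around a baseline mean beta (default 0.5)."""
    m0 = np.log2(base_beta / (1 - base_beta))
    lo = 1 / (1 + 2 ** (-(m0 - m_shift / 2)))
    hi = 1 / (1 + 2 ** (-(m0 + m_shift / 2)))
    return float(hi - lo)


def linked_validation_config(truth: dict, **overrides) -> SimulationConfig:
    """Build a validation-cohort config sharing a training bundle's planted
    DMP positions and shift directions (probe universe sizes must match)."""
    cfg_fields = dict(truth["config"])
    probe_ids = truth["dmp_probes"]
    idx = [int(p[2:]) for p in probe_ids]  # cg%08d -> index
    hypo = [truth["dmp_hypo_in_pos"][p] for p in probe_ids]
    cfg_fields.update(dmp_indices=idx, dmp_hypo=hypo)
    cfg_fields.update(overrides)
    if isinstance(cfg_fields.get("cnv_chroms"), list):
        cfg_fields["cnv_chroms"] = tuple(cfg_fields["cnv_chroms"])
    cfg_fields["cnv_events"] = [tuple(e) for e in cfg_fields.get("cnv_events", [])]
    return SimulationConfig(**cfg_fields)


def _simulate_methylation(cfg: SimulationConfig, rng: np.random.Generator):
    n = cfg.n_pos + cfg.n_neg
    probe_ids = [f"cg{i:08d}" for i in range(cfg.n_probes)]
    base = rng.uniform(0.15, 0.85, size=cfg.n_probes)
    if cfg.dmp_indices is not None:
        dmp_idx = np.asarray(sorted(cfg.dmp_indices), dtype=int)
        if len(dmp_idx) != cfg.n_dmp:
            raise ValueError("config field 'dmp_indices' length must equal n_dmp")
    else:
        dmp_idx = rng.choice(cfg.n_probes, size=cfg.n_dmp, replace=False)
        dmp_idx.sort()
    if cfg.dmp_hypo is not None:
        hypo = np.asarray(cfg.dmp_hypo, dtype=bool)
        if hypo.size != cfg.n_dmp:
            raise ValueError("config field 'dmp_hypo' length must equal n_dmp")
    else:
        n_hypo = int(round(cfg.frac_hypo * cfg.n_dmp))
        hypo = np.zeros(cfg.n_dmp, dtype=bool)
        hypo[rng.permutation(cfg.n_dmp)[:n_hypo]] = True

    mean_pos = base.copy()
    mean_neg = base.copy()
    # hypomethylated in SVZM+ => lower mean beta in the positive class
    shift = np.where(hypo, -cfg.effect_delta, cfg.effect_delta)
    mean_pos[dmp_idx] = base[dmp_idx] + shift / 2.0
    mean_neg[dmp_idx] = base[dmp_idx] - shift / 2.0
    mean_pos = np.clip(mean_pos, 1e-3 + cfg.effect_delta / 10, 1 - 1e-3 - cfg.effect_delta / 10)
    mean_neg = np.clip(mean_neg, 1e-3 + cfg.effect_delta / 10, 1 - 1e-3 - cfg.effect_delta / 10)

    disp = cfg.beta_dispersion
    betas = np.empty((cfg.n_probes, n))
    for j, mu in enumerate([mean_pos] * cfg.n_pos + [mean_neg] * cfg.n_neg):
        a = mu * disp
        b = (1 - mu) * disp
        betas[:, j] = rng.beta(a, b)
    betas = np.clip(betas, 1e-3, 1 - 1e-3)
    return probe_ids, betas, dmp_idx, hypo


def _simulate_survival(cfg: SimulationConfig, labels: np.ndarray, rng: np.random.Generator):
    n = labels.size
    x = (labels == POS).astype(float)
    u = rng.uniform(size=n)
    # inverse-CDF draw from a Weibull PH model with hazard multiplier exp(log_hr * x)
    t = cfg.weibull_scale * (-np.log(u) / np.exp(cfg.log_hr * x)) ** (1.0 / cfg.weibull_shape)
    event = np.ones(n, dtype=int)
    time = t.copy()
    if cfg.censor_rate > 0:
        # administrative uniform censoring on (0, c_max]; c_max solved so the
        # expected censored fraction over the realized times equals censor_rate
        def frac(c):
            return float(np.mean(np.minimum(t, c) / c))

        lo, hi = 1e-6, float(t.max()) * 100
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if frac(mid) > cfg.censor_rate:
                lo = mid
            else:
                hi = mid
        c = rng.uniform(0, 0.5 * (lo + hi), size=n)
        censored = c < t
        time = np.where(censored, c, t)
        event = (~censored).astype(int)
    time = np.maximum(time, 1e-3)
    return time, event


def _simulate_expression(cfg, m_values, probe_ids, dmp_idx, rng):
    n = m_values.shape[1]
    gene_ids = [f"EXPR{i:04d}" for i in range(cfg.n_genes)]
    # coupled genes map onto planted DMPs (cycled if fewer DMPs than genes)
    mapped_cpg = np.full(cfg.n_genes, -1)
    if cfg.n_coupled and len(dmp_idx):
        mapped_cpg[: cfg.n_coupled] = dmp_idx[np.arange(cfg.n_coupled) % len(dmp_idx)]
    # remaining genes get arbitrary (non-coupled) probes
    free = rng.choice(cfg.n_probes, size=cfg.n_genes, replace=cfg.n_probes < cfg.n_genes)
    mapped_cpg = np.where(mapped_cpg >= 0, mapped_cpg, free)

    log_depth = rng.normal(0.0, 0.15, size=n)  # library-size variation
    counts = np.empty((cfg.n_genes, n))
    rho = abs(cfg.coupling_rho)
    for g in range(cfg.n_genes):
        mv = m_values[mapped_cpg[g]]
        base = np.log(cfg.mean_counts) + rng.normal(0, 0.3)
        if g < cfg.n_coupled:
            # slope calibrated so corr(M, log expr) ~ -rho given NB noise on
            # the log scale of sd ~ sqrt(1/mu + alpha); the 1/(1-f) factor
            # compensates the CPM-normalization attenuation caused by coupled
            # genes (library-mass fraction f) shifting the totals with class
            sd_m = max(mv.std(), 1e-6)
            sigma_eps = np.sqrt(1.0 / cfg.mean_counts + cfg.nb_dispersion)
            f = min(cfg.n_coupled / cfg.n_genes, 0.8)
            slope = sigma_eps * rho / np.sqrt(1 - rho**2) / sd_m / (1 - f)
            eta = base - slope * (mv - mv.mean()) + log_depth
        else:
            eta = base + log_depth
        mu = np.exp(eta)
        # NB2 via gamma-Poisson mixture
        shape = 1.0 / cfg.nb_dispersion
        lam = rng.gamma(shape, mu / shape)
        counts[g] = rng.poisson(lam)
    expr = pd.DataFrame(counts.astype(int), index=gene_ids)
    gene_map = pd.DataFrame(
        {"cpg_id": [probe_ids[i] for i in mapped_cpg], "gene": gene_ids}
    )
    return expr, gene_map, mapped_cpg


def _simulate_cnv(cfg, labels, sample_ids, rng):
    rows = []
    for chrom in cfg.cnv_chroms:
        pos = (np.arange(cfg.cnv_probes_per_chrom) + 1) * 100_000
        for p in pos:
            rows.append((chrom, int(p)))
    grid = pd.DataFrame(rows, columns=["chrom", "pos"])
    n_probes = len(grid)

    def noise(n_cols):
        return rng.normal(0.0, cfg.cnv_noise_sd, size=(n_probes, n_cols))

    tumor = noise(len(sample_ids))
    event_truth = []
    for chrom, state, group, penetrance in cfg.cnv_events:
        shift = cfg.cnv_loss_shift if state == "loss" else cfg.cnv_gain_shift
        mask = (grid["chrom"] == chrom).values
        hit = (np.asarray(labels) == group) & (rng.uniform(size=len(sample_ids)) < penetrance)
        tumor[np.ix_(mask, hit)] += shift
        event_truth.append(
            {"chrom": chrom, "state": state, "group": group,
             "carriers": [s for s, h in zip(sample_ids, hit) if h]}
        )
    cnv = pd.concat([grid, pd.DataFrame(tumor, columns=sample_ids)], axis=1)
    normal_ids = [f"N{i:03d}" for i in range(cfg.n_normal)]
    ref = pd.concat([grid, pd.DataFrame(noise(cfg.n_normal), columns=normal_ids)], axis=1)
    return cnv, ref, event_truth


def _simulate_mutations(cfg, labels, sample_ids, rng):
    probs = cfg.variant_class_probs or {POS: _DEFAULT_CLASS_PROBS, NEG: _DEFAULT_CLASS_PROBS}
    records = []
    truth = []
    for sid, lab in zip(sample_ids, labels):
        grp_idx = 0 if lab == POS else 1
        mix = probs[lab]
        classes = list(mix)
        pvec = np.array([mix[c] for c in classes], dtype=float)
        pvec /= pvec.sum()
        for gene, rates in cfg.mutation_rates.items():
            mutated = rng.uniform() < rates[grp_idx]
            if mutated:
                if rng.uniform() < cfg.silent_frac:
                    vclass = "silent"
                else:
                    vclass = classes[rng.choice(len(classes), p=pvec)]
                truth.append({"sample_id": sid, "gene": gene, "variant_class": vclass})
                for pl in range(cfg.n_pipelines):
                    if rng.uniform() < cfg.pipeline_sensitivity:
                        records.append((sid, gene, f"pipe{pl + 1}", vclass))
            for pl in range(cfg.n_pipelines):
                if rng.uniform() < cfg.pipeline_false_rate:
                    vclass = classes[rng.choice(len(classes), p=pvec)]
                    records.append((sid, gene, f"pipe{pl + 1}", vclass))
    muts = pd.DataFrame(records, columns=["sample_id", "gene", "pipeline", "variant_class"])
    muts["silent"] = muts["variant_class"] == "silent"
    return muts, truth


def _simulate_raters(cfg, labels, sample_ids, rng):
    cols = {}
    for r in range(cfg.n_raters):
        flip = rng.uniform(size=len(sample_ids)) < cfg.rater_error
        lab = np.asarray(labels, dtype=object).copy()
        lab[flip] = np.where(np.asarray(labels)[flip] == POS, NEG, POS)
        cols[f"rater{r + 1}"] = lab
    return pd.DataFrame(cols, index=pd.Index(sample_ids, name="sample_id"))


def generate_cohort(config: SimulationConfig) -> CohortBundle:
    """Generate a fully linked synthetic cohort (see module docstring).

    Deterministic: the same ``config`` (including ``seed``) yields an
    identical bundle.
    """
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(7)
    rng_meth, rng_surv, rng_expr, rng_cnv, rng_mut, rng_rat, rng_cov = (
        np.random.default_rng(s) for s in streams
    )

    n = config.n_pos + config.n_neg
    sample_ids = [f"S{i:03d}" for i in range(1, n + 1)]
    labels = np.array([POS] * config.n_pos + [NEG] * config.n_neg, dtype=object)

    probe_ids, betas, dmp_idx, hypo = _simulate_methylation(config, rng_meth)
    beta_df = pd.DataFrame(betas, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids)
    m_values = beta_to_m(betas)

    time, event = _simulate_survival(config, labels, rng_surv)
    expr, gene_map, _ = _simulate_expression(config, m_values, probe_ids, dmp_idx, rng_expr)
    expr.columns = sample_ids
    cnv, cnv_ref, cnv_truth = _simulate_cnv(config, labels, sample_ids, rng_cnv)
    muts, mut_truth = _simulate_mutations(config, labels, sample_ids, rng_mut)
    raters = _simulate_raters(config, labels, sample_ids, rng_rat)

    mri = labels.copy()
    if config.mri_error > 0:
        flip = rng_cov.uniform(size=n) < config.mri_error
        mri[flip] = np.where(labels[flip] == POS, NEG, POS)

    # clinical covariates, independent of outcome by default
    age = rng_cov.normal(59.0, 9.0, size=n).round(1)
    kps80 = (rng_cov.uniform(size=n) < 0.65).astype(int)
    tmz = (rng_cov.uniform(size=n) < 0.65).astype(int)
    mgmt = (rng_cov.uniform(size=n) < 0.4).astype(int)
    dose60 = (rng_cov.uniform(size=n) < 0.75).astype(int)
    surgery = rng_cov.choice(["subtotal", "total", "biopsy"], p=[0.5, 0.4, 0.1], size=n)

    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "mri_label": mri,
            "time_months": np.round(time, 4),
            "event": event,
            "age": age,
            "kps80": kps80,
            "tmz": tmz,
            "mgmt": mgmt,
            "dose60": dose60,
            "surgery": surgery,
        }
    )

    # annotate planted DMP probes with the coupled gene symbols
    ann = pd.DataFrame(
        {
            "chrom": "chr4",
            "pos": np.arange(len(probe_ids)) * 1000,
            "gene": "",
            "sex_chrom": False,
            "snp_overlap": False,
            "repetitive": False,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    gm = gene_map.groupby("cpg_id")["gene"].apply(lambda g: ";".join(sorted(g)))
    ann.loc[gm.index, "gene"] = gm.values

    truth = {
        "labels": dict(zip(sample_ids, labels)),
        "dmp_probes": [probe_ids[i] for i in dmp_idx],
        "dmp_hypo_in_pos": {probe_ids[i]: bool(h) for i, h in zip(dmp_idx, hypo)},
        "coupled_genes": list(expr.index[: config.n_coupled]),
        "cnv_events": cnv_truth,
        "mutations": mut_truth,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
        },
    }

    return CohortBundle(
        methylation=MethylationMatrix(beta_df, ann),
        samples=samples,
        expression=expr,
        gene_cpg_map=gene_map,
        cnv_input=cnv,
        cnv_reference=cnv_ref,
        mutations=muts,
        raters=raters,
        truth=truth,
    )


def write_bundle(bundle: CohortBundle, outdir) -> dict:
    """Write every layer of the bundle as TSV (plus a JSON truth file);
    returns the mapping of layer name to path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "methylation": outdir / "methylation.tsv",
        "annotation": outdir / "probe_annotation.tsv",
        "samples": outdir / "samples.tsv",
        "expression": outdir / "expression.tsv",
        "gene_cpg_map": outdir / "gene_cpg_map.tsv",
        "cnv_input": outdir / "cnv_probes.tsv",
        "cnv_reference": outdir / "cnv_reference.tsv",
        "mutations": outdir / "mutations.tsv",
        "raters": outdir / "raters.tsv",
        "truth": outdir / "truth.json",
    }
    bundle.methylation.beta.to_csv(paths["methylation"], sep="\t", index_label="probe_id")
    bundle.methylation.annotation.to_csv(paths["annotation"], sep="\t", index_label="probe_id")
    bundle.samples.to_csv(paths["samples"], sep="\t", index=False)
    bundle.expression.to_csv(paths["expression"], sep="\t", index_label="gene_id")
    bundle.gene_cpg_map.to_csv(paths["gene_cpg_map"], sep="\t", index=False)
    bundle.cnv_input.to_csv(paths["cnv_input"], sep="\t", index=False)
    bundle.cnv_reference.to_csv(paths["cnv_reference"], sep="\t", index=False)
    bundle.mutations.to_csv(paths["mutations"], sep="\t", index=False)
    bundle.raters.to_csv(paths["raters"], sep="\t")
    with open(paths["truth"], "w") as fh:
        json.dump(bundle.truth, fh, indent=1, default=str)
    return {k: str(v) for k, v in paths.items()}
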