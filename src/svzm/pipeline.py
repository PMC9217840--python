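"""Stage orchestration for the two-cohort SVZM workflow.

Stages: simulate -> preprocess -> discover -> classify -> survival /
agreement / cnv / mutations / integrate. Each stage reads its inputs from the
output directory of earlier stages, writes result tables plus a JSON manifest
(input checksums, parameters, seed) and is deterministic for a fixed config.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from svzm import catstats, cnv, integration, mutations, preprocess, signature, survival
from svzm.simulate import SimulationConfig, generate_cohort, write_bundle, POS

log = logging.getLogger(__name__)

DEFAULT_PARAMS = {
    "alpha_dmp": 0.001,
    "k_signature": 15,
    "mad_top": 30_000,
    "n_perm": 500,
    "fdr": 0.05,
    "min_pipelines": 3,
    "panel_fdr": 0.10,
    "n_trees": 500,
    "seed": 0,
}

STAGE_DEPS = {
    "simulate": [],
    "preprocess": ["simulate"],
    "discover": ["preprocess"],
    "classify": ["discover"],
    "survival": ["classify"],
    "agreement": ["simulate"],
    "cnv": ["simulate", "classify"],
    "mutations": ["simulate", "classify"],
    "integrate": ["preprocess", "classify"],
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _manifest(outdir: Path, stage: str, inputs: list, params: dict, outputs: list) -> None:
    man = {
        "stage": stage,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()},
        "params": params,
        "outputs": [str(o) for o in outputs],
        "finished": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(outdir / f"manifest_{stage}.json", "w") as fh:
        json.dump(man, fh, indent=1, default=str)


def _require(outdir: Path, stage: str) -> None:
    for dep in STAGE_DEPS[stage]:
        if not (outdir / f"manifest_{dep}.json").exists():
            raise RuntimeError(f"stage '{stage}' requires prior stage '{dep}' (missing manifest)")


def run_stage(stage: str, config: dict) -> dict:
    """Run one named stage; returns a dict of output paths/results."""
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    outdir = Path(config.get("outdir", "svzm_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    _require(outdir, stage)
    t0 = time.time()
    fn = _STAGES[stage]
    out = fn(config, params, outdir)
    log.info("stage %s finished in %.1fs", stage, time.time() - t0)
    return out


def _stage_simulate(config, params, outdir):
    sim_cfg = SimulationConfig(**config.get("simulate", {}), seed=params["seed"])
    bundle = generate_cohort(sim_cfg)
    paths = write_bundle(bundle, outdir / "cohort")
    _manifest(outdir, "simulate", [], {**params, "simulate": config.get("simulate", {})},
              list(paths.values()))
    return paths


def _load_cohort(outdir: Path):
    d = outdir / "cohort"
    m = preprocess.read_methylation_tsv(d / "methylation.tsv", d / "probe_annotation.tsv")
    samples = pd.read_csv(d / "samples.tsv", sep="\t")
    return m, samples, d


def _stage_preprocess(config, params, outdir):
    m, samples, d = _load_cohort(outdir)
    m = preprocess.filter_probes(m)
    k = min(params["mad_top"], m.n_probes)
    m = preprocess.top_mad_probes(m, k)
    out = outdir / "preprocessed_beta.tsv"
    preprocess.write_methylation_tsv(m, out, outdir / "preprocessed_annotation.tsv")
    _manifest(outdir, "preprocess", [d / "methylation.tsv"], params, [out])
    return {"beta": str(out)}


def _load_preprocessed(outdir: Path):
    return preprocess.read_methylation_tsv(
        outdir / "preprocessed_beta.tsv", outdir / "preprocessed_annotation.tsv"
    )


def _stage_discover(config, params, outdir):
    m = _load_preprocessed(outdir)
    _, samples, _ = _load_cohort(outdir)
    labels = samples.set_index("sample_id")["mri_label"]
    sig, dmp, stable = signature.discover_signature(
        m, labels, alpha=params["alpha_dmp"], k=params["k_signature"],
        n_trees=params["n_trees"], seed=params["seed"],
    )
    sig_path = outdir / "signature.json"
    sig.to_json(sig_path)
    dmp.to_csv(outdir / "dmp_table.tsv", sep="\t")
    pd.Series(stable, name="probe_id").to_csv(outdir / "stable_probes.tsv", sep="\t", index=False)
    _manifest(outdir, "discover", [outdir / "preprocessed_beta.tsv"], params, [sig_path])
    return {"signature": str(sig_path), "n_dmp": int(dmp["is_dmp"].sum()), "n_stable": len(stable)}


def _stage_classify(config, params, outdir):
    m, samples, _ = _load_cohort(outdir)
    sig = signature.SignatureModel.from_json(outdir / "signature.json")
    mode = config.get("classify_mode", "train_clustering")
    labels = signature.classify_svzm(m, sig, mode=mode)
    out = outdir / "svzm_labels.tsv"
    labels.rename("svzm_label").to_csv(out, sep="\t", index_label="sample_id")
    _manifest(outdir, "classify", [outdir / "signature.json"], params, [out])
    return {"labels": str(out)}


def _stage_survival(config, params, outdir):
    _, samples, _ = _load_cohort(outdir)
    svzm = pd.read_csv(outdir / "svzm_labels.tsv", sep="\t").set_index("sample_id")["svzm_label"]
    df = samples.set_index("sample_id")
    df["svzm_pos"] = (svzm.loc[df.index] == POS).astype(int)
    screen = survival.univariable_screen(
        df, ["svzm_pos", "age", "kps80", "tmz", "mgmt", "dose60"]
    )
    out = outdir / "univariable_screen.tsv"
    screen.to_csv(out, sep="\t")
    km = survival.km_estimate(df.assign(group=svzm.loc[df.index]), "group")
    medians = {g: v["median"] for g, v in km.items()}
    with open(outdir / "km_medians.json", "w") as fh:
        json.dump(medians, fh, indent=1, default=str)
    _manifest(outdir, "survival", [outdir / "svzm_labels.tsv"], params, [out])
    return {"screen": str(out), "km_medians": medians}


def _stage_agreement(config, params, outdir):
    _, samples, d = _load_cohort(outdir)
    raters = pd.read_csv(d / "raters.tsv", sep="\t", index_col=0)
    icc_res = catstats.icc(raters)
    cons = catstats.consensus_rating(raters)
    out = outdir / "agreement.json"
    with open(out, "w") as fh:
        json.dump(
            {"icc": icc_res["icc"], "icc_ci95": icc_res["ci95"],
             "consensus_fraction": cons["consensus_fraction"]},
            fh, indent=1,
        )
    _manifest(outdir, "agreement", [d / "raters.tsv"], params, [out])
    return {"agreement": str(out)}


def _stage_cnv(config, params, outdir):
    _, samples, d = _load_cohort(outdir)
    track = pd.read_csv(d / "cnv_probes.tsv", sep="\t")
    ref = pd.read_csv(d / "cnv_reference.tsv", sep="\t")
    svzm = pd.read_csv(outdir / "svzm_labels.tsv", sep="\t").set_index("sample_id")["svzm_label"]
    sample_cols = [c for c in track.columns if c not in ("chrom", "pos")]
    ref_cols = [c for c in ref.columns if c not in ("chrom", "pos")]
    ref_means = []
    for i, c in enumerate(ref_cols):
        for s in cnv.segment_track(ref, c, seed=params["seed"] + i):
            ref_means.append(s.mean_log2ratio)
    cuts = cnv.auto_thresholds(ref_means)
    segs = {}
    for i, c in enumerate(sample_cols):
        segs[c] = cnv.call_states(
            cnv.segment_track(track, c, seed=params["seed"] + 1000 + i), cuts
        )
    bins = cnv.make_bins(track)
    comp = cnv.group_cnv_comparison(segs, svzm.loc[sample_cols], bins)
    seg_out = outdir / "cnv_segments.tsv"
    cnv.segments_to_frame(segs).to_csv(seg_out, sep="\t", index=False)
    comp_out = outdir / "cnv_group_comparison.tsv"
    comp.to_csv(comp_out, sep="\t", index=False)
    _manifest(outdir, "cnv", [d / "cnv_probes.tsv"], {**params, **cuts}, [seg_out, comp_out])
    return {"segments": str(seg_out), "comparison": str(comp_out), "thresholds": cuts}


def _stage_mutations(config, params, outdir):
    _, samples, d = _load_cohort(outdir)
    calls = pd.read_csv(d / "mutations.tsv", sep="\t")
    svzm = pd.read_csv(outdir / "svzm_labels.tsv", sep="\t").set_index("sample_id")["svzm_label"]
    pipelines = sorted(calls["pipeline"].unique())
    cons = mutations.pipeline_consensus(
        calls, list(svzm.index), pipelines, min_pipelines=params["min_pipelines"]
    )
    enr = mutations.per_gene_enrichment(cons, svzm, q=params["panel_fdr"])
    burden = mutations.mutation_burden_test(cons, svzm)
    inter = mutations.mutation_type_interaction(calls, svzm)
    enr_out = outdir / "mutation_enrichment.tsv"
    enr.to_csv(enr_out, sep="\t")
    inter.to_csv(outdir / "mutation_type_interaction.tsv", sep="\t")
    _manifest(outdir, "mutations", [d / "mutations.tsv"], params, [enr_out])
    return {"enrichment": str(enr_out), "burden_p": burden["p"]}


def _stage_integrate(config, params, outdir):
    m = _load_preprocessed(outdir)
    _, samples, d = _load_cohort(outdir)
    svzm = pd.read_csv(outdir / "svzm_labels.tsv", sep="\t").set_index("sample_id")["svzm_label"]
    counts = pd.read_csv(d / "expression.tsv", sep="\t", index_col=0)
    gene_map = pd.read_csv(d / "gene_cpg_map.tsv", sep="\t")
    sam = integration.sam_test(
        m.m_values(), svzm.loc[m.sample_ids],
        n_perm=params["n_perm"], fdr_target=params["fdr"], seed=params["seed"],
    )
    de = integration.differential_expression(counts, svzm.loc[counts.columns], fdr=params["fdr"])
    corr = integration.meth_expr_correlation(m.m_values(), counts, gene_map)
    rank = integration.gene_cpg_rank(sam.called, m.annotation)
    sam_out = outdir / "sam_called.tsv"
    pd.DataFrame(
        {"probe_id": sam.called,
         "d": [sam.d[p] for p in sam.called],
         "direction": [sam.direction[p] for p in sam.called]}
    ).to_csv(sam_out, sep="\t", index=False)
    de["table"].to_csv(outdir / "differential_expression.tsv", sep="\t")
    corr.to_csv(outdir / "meth_expr_correlation.tsv", sep="\t", index=False)
    rank.rename("n_cpgs").to_csv(outdir / "gene_cpg_rank.tsv", sep="\t", index_label="gene")
    _manifest(outdir, "integrate", [d / "expression.tsv"], params, [sam_out])
    return {
        "n_sam_called": len(sam.called),
        "sam_fdr": sam.fdr,
        "n_deg": int(de["table"]["significant"].sum()),
    }


_STAGES = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "discover": _stage_discover,
    "classify": _stage_classify,
    "survival": _stage_survival,
    "agreement": _stage_agreement,
    "cnv": _stage_cnv,
    "mutations": _stage_mutations,
    "integrate": _stage_integrate,
}

ALL_STAGES = list(_STAGES)


def run_all(config: dict) -> dict:
    """Run every stage in dependency order; returns per-stage outputs."""
    return {stage: run_stage(stage, config) for stage in ALL_STAGES}
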