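"""End-to-end orchestration: simulate/ingest -> prep -> networks ->
univariate inference -> MVPA -> reports.

A run is fully described by a :class:`PipelineConfig` (loadable from
YAML) and a master seed.  Stage randomness is fanned out from the master
seed through ``numpy.random.SeedSequence([seed, stage_counter])`` with a
fixed counter per stage, so a run is reproducible end to end and stages
are individually re-runnable.  Every output file carries the config hash
in a comment header; the run manifest records a checksum per artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import clinical, io
from .connectivity import GCConfig, build_connectivity, build_ec_matrix, vectorize_edges
from .containers import RegionTimeSeries
from .inference import (
    EdgeFeatureTable,
    one_sample_maxt_perm,
    summarize_significant_edges,
    two_sample_maxt_perm,
)
from .mvpa import (
    SVMConfig,
    combine_features,
    permutation_accuracy_test,
    top_weight_edges,
    univariate_overlap,
)
from .prep import PrepConfig, clean_series, discard_initial_volumes
from .synthetic import CohortSpec, simulate_clinical_table, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "make_demo_dataset",
    "cohort_spec_for_preset",
    "ec_feature_table",
]

# seed fan-out counters per stage
_SEED_SIM, _SEED_INFER, _SEED_MVPA = 0, 1, 2


@dataclass
class PipelineConfig:
    """Declarative description of a full analysis run."""

    output_dir: str = "twinconn_run"
    input_manifest: str | None = None  # None -> simulate the cohort
    preset: str = "tiny"  # cohort preset when simulating
    seed: int = 0
    n_discard: int = 10
    band: tuple[float, float] = (0.01, 0.1)
    standardize_gc: bool = True
    inference_n_perm: int = 1000
    alpha: float = 0.05
    mvpa_n_perm: int = 1000
    svm_c: float = 1.0
    top_weight_fraction: float = 0.01
    comparisons: Sequence[tuple[str, str]] = (("SZ", "HC"), ("COTWIN", "HC"), ("SZ", "COTWIN"))
    feature_sets: Sequence[str] = ("ec", "fc", "ec+fc")
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if isinstance(cfg.band, list):
            cfg.band = tuple(cfg.band)
        cfg.comparisons = tuple(tuple(c) for c in cfg.comparisons)
        return cfg

    def config_hash(self) -> str:
        # analysis parameters only: where outputs land must not change
        # what they contain
        params = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        blob = json.dumps(params, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def cohort_spec_for_preset(preset: str, seed: int, n_volumes: int = 180) -> CohortSpec:
    """Built-in synthetic cohort presets.

    ``tiny``: 30 regions, 3 x 10 subjects — fast smoke-scale runs.
    ``full``: 272 regions, 3 x 20 subjects.
    ``null``: like tiny but with no planted group differences.

    The non-null presets plant +0.4 on nine directed couplings for the SZ
    group (picked up by the Granger stage) and +0.3 innovation covariance
    on a disjoint set of region pairs (picked up by the Pearson stage) —
    directed and undirected alterations are disjoint by construction.
    """
    ec_edges = {(2 * k, 2 * k + 1): 0.4 for k in range(9)}
    if preset == "tiny":
        fc_pairs = {(2 * k, 2 * k + 1): 0.3 for k in range(9, 15)}
        return CohortSpec(
            n_regions=30,
            n_volumes=n_volumes,
            groups=(("HC", 10), ("COTWIN", 10), ("SZ", 10)),
            group_coupling_deltas={"SZ": ec_edges},
            group_noise_deltas={"SZ": fc_pairs},
            seed=seed,
        )
    if preset == "full":
        fc_pairs = {(2 * k, 2 * k + 1): 0.3 for k in range(9, 18)}
        return CohortSpec(
            n_regions=272,
            n_volumes=n_volumes,
            group_coupling_deltas={"SZ": ec_edges},
            group_noise_deltas={"SZ": fc_pairs},
            seed=seed,
        )
    if preset == "null":
        return CohortSpec(
            n_regions=30,
            n_volumes=n_volumes,
            groups=(("HC", 10), ("COTWIN", 10), ("SZ", 10)),
            seed=seed,
        )
    raise ValueError(f"unknown preset {preset!r}")


def make_demo_dataset(preset: str, out_dir, seed: int = 0) -> Path:
    """Write an on-disk synthetic dataset: series TSVs, manifest, clinical TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = cohort_spec_for_preset(preset, seed)
    subjects = simulate_cohort(spec)
    series_dir = out / "series"
    series_dir.mkdir(exist_ok=True)
    entries = []
    for s in subjects:
        p = io.write_series_tsv(s, series_dir / f"{s.subject_id}.tsv")
        entries.append(
            {"subject_id": s.subject_id, "group": s.group, "series": str(p.relative_to(out))}
        )
    io.write_manifest(entries, out / "manifest.tsv")
    sizes = {label: n for label, n in spec.groups}
    clin = simulate_clinical_table(clinical.clinical_score_spec(seed=seed), sizes)
    clin.to_csv(out / "clinical.tsv", sep="\t", index=False)
    return out


def ec_feature_table(
    subjects: Sequence[RegionTimeSeries], gc_config: GCConfig = GCConfig()
) -> EdgeFeatureTable:
    """Subjects x directed-edges table of EC estimates (vectorized edges)."""
    rows, index = [], None
    for s in subjects:
        vec, index = vectorize_edges(build_ec_matrix(s, gc_config), "directed", s.region_ids)
        rows.append(vec)
    return EdgeFeatureTable(np.vstack(rows), [s.group for s in subjects], index)


def _load_subjects(config: PipelineConfig) -> list[RegionTimeSeries]:
    if config.input_manifest:
        manifest = io.read_manifest(config.input_manifest)
        base = Path(config.input_manifest).parent
        return [io.read_series_tsv(base / row["series"]) for _, row in manifest.iterrows()]
    # the cohort spec consumes the master seed directly (stage counter 0
    # is reserved for it inside simulate_cohort's per-subject fan-out)
    spec = cohort_spec_for_preset(config.preset, config.seed)
    return simulate_cohort(spec)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns the run report (also written as JSON).

    Artifacts, per comparison: two-sample edge reports and null dumps for
    EC and Fisher-z FC; MVPA result JSONs, top-weight edge TSVs and
    univariate-overlap reports for each configured feature set; plus
    per-group one-sample EC edge reports, the clinical summary table, and
    a checksummed output manifest.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    stamp = f"config_hash={chash}"
    report: dict = {"config_hash": chash, "seed": config.seed, "artifacts": {}}

    def register(path: Path) -> None:
        report["artifacts"][str(path.relative_to(out))] = _sha256(path)

    # ---- simulate / ingest + prep -------------------------------------
    subjects = _load_subjects(config)
    groups = [s.group for s in subjects]
    prep_cfg = PrepConfig(n_discard=config.n_discard, band=config.band)
    cleaned = []
    for s in subjects:
        s = discard_initial_volumes(s, prep_cfg.n_discard)
        cleaned.append(clean_series(s, config=prep_cfg))
    logger.info("prepared %d subjects (%d regions x %d volumes)",
                len(cleaned), cleaned[0].n_regions, cleaned[0].n_timepoints)

    # ---- connectivity --------------------------------------------------
    gc_cfg = GCConfig(standardize=config.standardize_gc)
    ec_rows, fcz_rows = [], []
    ec_index = fc_index = None
    for s in cleaned:
        conn = build_connectivity(s, gc_cfg)
        ec_vec, ec_index = vectorize_edges(conn.ec, "directed", conn.region_ids)
        z = conn.fc_z
        np.fill_diagonal(z, 0.0)  # diagonal is undefined and never vectorized
        fcz_vec, fc_index = vectorize_edges(z, "undirected", conn.region_ids)
        ec_rows.append(ec_vec)
        fcz_rows.append(fcz_vec)
    ec_table = EdgeFeatureTable(np.vstack(ec_rows), groups, ec_index)
    fcz_table = EdgeFeatureTable(np.vstack(fcz_rows), groups, fc_index)

    infer_seed = np.random.SeedSequence([config.seed, _SEED_INFER])
    mvpa_seed = np.random.SeedSequence([config.seed, _SEED_MVPA])
    infer_children = iter(infer_seed.spawn(512))
    mvpa_children = iter(mvpa_seed.spawn(512))

    # ---- one-sample presence tests per group (EC) ----------------------
    for label in dict.fromkeys(groups):
        sub = ec_table.subset([label])
        res = one_sample_maxt_perm(sub, config.inference_n_perm, next(infer_children),
                                   alpha=config.alpha)
        rep = summarize_significant_edges(res, ec_index)
        path = out / f"onesample_ec_{label}.tsv"
        _write_report_df(rep.table, path, stamp)
        register(path)
        report.setdefault("one_sample_significant", {})[label] = int(res.significant.sum())

    # ---- two-sample comparisons ---------------------------------------
    for ga, gb in config.comparisons:
        for kind, table in (("ec", ec_table), ("fc", fcz_table)):
            res = two_sample_maxt_perm(table, ga, gb, config.inference_n_perm,
                                       next(infer_children), alpha=config.alpha)
            rep = summarize_significant_edges(res, table.edge_index, table, ga, gb)
            tag = f"{kind}_{ga}_vs_{gb}"
            path = out / f"twosample_{tag}.tsv"
            _write_report_df(rep.table, path, stamp)
            register(path)
            null_path = out / f"null_maxt_{tag}.tsv"
            _write_null_dump(res.null_max_abs_t, null_path, stamp)
            register(null_path)
            key = f"{ga}_vs_{gb}"
            report.setdefault("two_sample", {}).setdefault(key, {})[kind] = {
                "n_significant": int(res.significant.sum()),
                "sign_patterns": rep.sign_pattern_counts,
            }
            if kind == "ec":
                sig_ec_edges = [table.edge_index[e] for e in np.flatnonzero(res.significant)]

        # ---- MVPA per feature set -------------------------------------
        keep = [i for i, g in enumerate(groups) if g in (ga, gb)]
        labels = np.array([groups[i] for i in keep])
        blocks_all = {
            "ec": (ec_table.values[keep], ec_index),
            "fc": (fcz_table.values[keep], fc_index),
        }
        svm_cfg = SVMConfig(c=config.svm_c)
        for fset in config.feature_sets:
            names = fset.split("+")
            assembly = combine_features({n: blocks_all[n] for n in names})
            res = permutation_accuracy_test(assembly.x, labels, config.mvpa_n_perm,
                                            next(mvpa_children), svm_cfg)
            tops = top_weight_edges(res.mean_weights, config.top_weight_fraction,
                                    assembly.index)
            mv = {
                "accuracy": res.accuracy,
                "p_value": res.p_value,
                "p_formatted": res.formatted_p(),
                "n_perm": res.n_perm,
                "n_features": assembly.n_features,
            }
            if "ec" in names:
                top_ec = [e for blk, e in (t[0] for t in tops) if blk == "ec"]
                ov = univariate_overlap(top_ec, sig_ec_edges)
                mv["top_weight_overlap_with_univariate"] = ov.n_overlap
            report.setdefault("mvpa", {}).setdefault(f"{ga}_vs_{gb}", {})[fset] = mv
            wpath = out / f"weights_{fset.replace('+', '_')}_{ga}_vs_{gb}.tsv"
            with open(wpath, "w") as fh:
                fh.write(f"# {stamp}\nblock\tedge\tweight\n")
                for (blk, edge), w in tops:
                    fh.write(f"{blk}\t{edge}\t{io.FLOAT_FMT % w}\n")
            register(wpath)

    # ---- clinical table ------------------------------------------------
    clin_path = out / "clinical_summary.tsv"
    with open(clin_path, "w") as fh:
        fh.write(f"# {stamp}\n")
        clinical.summary_table().to_csv(fh, sep="\t", index=False, float_format="%.6g")
    register(clin_path)

    report_path = out / "run_report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    report["artifacts"][str(report_path.relative_to(out))] = "self"
    return report


def _write_report_df(df: pd.DataFrame, path: Path, stamp: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {stamp}\n")
        if len(df):
            df.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        else:
            fh.write("source\ttarget\ttrue_t\tp_corrected\tsign\n")


def _write_null_dump(null_max: np.ndarray, path: Path, stamp: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {stamp}\nperm\tmax_abs_t\n")
        for k, v in enumerate(null_max):
            fh.write(f"{k}\t{io.FLOAT_FMT % v}\n")
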