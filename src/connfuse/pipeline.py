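"""End-to-end orchestration: epochs -> connectivity -> classification.

``run_pipeline`` executes the full analysis on a manifest of epoched
subjects: group time-frequency comparison, per-subject PLI and PDC
connectivity, feature fusion, the three selection strategies, the
permutation significance of the winning classifier, and the per-feature
group comparison.  Every stage writes its intermediates as plain-text
tables under the output directory, and everything is deterministic
given the configured seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from ._exceptions import ValidationError
from .classify import (
    FeatureTable, build_feature_table, compare_selected_features,
    format_descriptor, modified_permutation_test, select_and_classify_combined,
    select_and_classify_single, write_feature_table,
)
from .epochs import EpochSet, read_epochset, read_manifest, write_epochset, write_manifest
from .mvar import (
    PDC_TAG, apply_threshold, band_average_pdc, ensemble_covariance,
    fit_mvar, select_order_bic, surrogate_threshold,
)
from .pli import PLI_TAG, pli_matrix
from .synthetic import StudyConfig, simulate_two_group_study
from .timefreq import build_wavelet_bank, cluster_permutation_test, morlet_transform, power_db

log = logging.getLogger("connfuse")


@dataclass
class PipelineConfig:
    """All pipeline settings; the defaults are the study settings."""

    manifest: str = ""
    out_dir: str = "connfuse_out"
    band: tuple[float, float] = (4.0, 7.0)
    window: tuple[float, float] = (0.1, 0.6)
    baseline: tuple[float, float] = (-0.2, -0.1)
    stats_window: tuple[float, float] = (-0.2, 1.0)
    tf_channels: tuple[str, ...] = ("F3", "F4")
    wavelet_f: tuple[float, float] = (3.9, 40.0)
    wavelet_points: int = 50
    wavelet_cycles: tuple[float, float] = (3.0, 11.4)
    mvar_order: int | str = "auto"  # "auto" -> BIC over p_range
    p_range: tuple[int, int] = (1, 15)
    freq_step: float = 0.25
    surrogate_enabled: bool = True
    n_surrogates: int = 5000
    surrogate_alpha: float = 0.05
    n_max: int = 50
    l_max: int = 50
    rank_on_full_data: bool = False
    svm_c: float = 1.0
    positive_class: str = "SZ"
    n_perm_cluster: int = 10_000
    pixel_alpha: float = 0.01
    fw_alpha: float = 0.05
    n_perm_classifier: int = 10_000
    fdr_q: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mvar_order != "auto" and int(self.mvar_order) < 1:
            raise ValidationError("mvar_order must be 'auto' or a positive integer")
        for name in ("n_surrogates", "n_max", "l_max", "n_perm_cluster",
                     "n_perm_classifier"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        for name in ("surrogate_alpha", "pixel_alpha", "fw_alpha", "fdr_q"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValidationError(f"{name} must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("band", "window", "baseline", "stats_window", "wavelet_f",
                    "wavelet_cycles", "p_range", "tf_channels"):
            if key in doc and isinstance(doc[key], list):
                doc[key] = tuple(doc[key])
        return cls(**doc)


def _write_matrix_tsv(path: Path, values: np.ndarray, labels: tuple[str, ...]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t" + "\t".join(labels) + "\n")
        for lab, row in zip(labels, values):
            fh.write(lab + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def load_subjects(manifest_path: str | Path) -> list[EpochSet]:
    base = Path(manifest_path).parent
    subjects = []
    for entry in read_manifest(manifest_path):
        p = Path(entry["path"])
        if not p.is_absolute():
            p = base / p
        subjects.append(read_epochset(p))
    if len({s.group for s in subjects}) < 2:
        raise ValidationError("manifest must contain two subject groups")
    return subjects


def stage_simulate(study: StudyConfig, out_dir: str | Path) -> Path:
    """Materialize a simulated study as epoch containers plus manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = simulate_two_group_study(study)
    entries = []
    for rec in result["subjects"]:
        stem = out / "epochs" / rec["subject_id"]
        write_epochset(rec["epochs"], stem)
        entries.append({"subject_id": rec["subject_id"], "group": rec["group"],
                        "path": str(stem.relative_to(out))})
    manifest = write_manifest(entries, out / "manifest.json")
    (out / "ground_truth.json").write_text(
        json.dumps(result["ground_truth"], indent=1), encoding="utf-8")
    return manifest


def stage_tfr(subjects: list[EpochSet], cfg: PipelineConfig, out: Path) -> dict:
    """Group TF maps (selected channels averaged) and the cluster test."""
    bank = build_wavelet_bank(cfg.wavelet_f[0], cfg.wavelet_f[1],
                              cfg.wavelet_points, cfg.wavelet_cycles[0],
                              cfg.wavelet_cycles[1], fs=subjects[0].fs)
    groups = sorted({s.group for s in subjects})
    chans = [c for c in cfg.tf_channels if c in subjects[0].montage.labels]
    if not chans:
        chans = list(subjects[0].montage.labels)
    maps = {g: [] for g in groups}
    for s in subjects:
        coeffs = morlet_transform(s, bank, chans)
        maps[s.group].append(power_db(coeffs, cfg.baseline))
    result = cluster_permutation_test(
        maps[groups[0]], maps[groups[1]], n_perm=cfg.n_perm_cluster,
        pixel_alpha=cfg.pixel_alpha, fw_alpha=cfg.fw_alpha,
        time_window=cfg.stats_window, seed=cfg.seed,
    )
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / "tf_sig_mask.tsv", result.sig_mask.astype(int),
               fmt="%d", delimiter="\t")
    np.savetxt(out / "tf_t_map.tsv", result.t_map, fmt="%.6g", delimiter="\t")
    summary = {
        "groups": groups,
        "channels_averaged": chans,
        "n_clusters_significant": len(result.clusters),
        "cluster_sizes": [size for _, size in result.clusters],
        "cluster_size_threshold": result.cluster_threshold,
        "n_pixels_tested": int(result.t_map.size),
    }
    (out / "tf_cluster_test.json").write_text(json.dumps(summary, indent=1),
                                              encoding="utf-8")
    return {"result": result, "summary": summary, "bank": bank}


def stage_connectivity(subjects: list[EpochSet], cfg: PipelineConfig,
                       out: Path) -> tuple[list, list]:
    """Per-subject PLI and (optionally surrogate-thresholded) PDC matrices."""
    bank = build_wavelet_bank(cfg.wavelet_f[0], cfg.wavelet_f[1],
                              cfg.wavelet_points, cfg.wavelet_cycles[0],
                              cfg.wavelet_cycles[1], fs=subjects[0].fs)
    ss = np.random.SeedSequence([cfg.seed, 0xC0]).spawn(len(subjects))
    out.mkdir(parents=True, exist_ok=True)
    pli_list, pdc_list = [], []
    for s, seed_seq in zip(subjects, ss):
        t0 = time.perf_counter()
        plim = pli_matrix(s, bank, cfg.band, cfg.window)
        if cfg.mvar_order == "auto":
            order = select_order_bic(s, cfg.window, cfg.p_range)
        else:
            order = int(cfg.mvar_order)
        covs = ensemble_covariance(s, cfg.window, max_lag=order)
        model = fit_mvar(covs, order)
        pdcm = band_average_pdc(model, cfg.band, cfg.freq_step)
        if cfg.surrogate_enabled:
            sub_seed = int(seed_seq.generate_state(1)[0] % (2**31))
            null = surrogate_threshold(
                s, cfg.window, cfg.band, order, cfg.n_surrogates,
                cfg.surrogate_alpha, seed=sub_seed, freq_step=cfg.freq_step,
            )
            pdcm = apply_threshold(pdcm, null)
        pli_list.append(plim)
        pdc_list.append(pdcm)
        _write_matrix_tsv(out / f"{s.subject_id}_pli.tsv", plim.values,
                          s.montage.labels)
        _write_matrix_tsv(out / f"{s.subject_id}_pdc.tsv", pdcm.values,
                          s.montage.labels)
        log.info("connectivity subject=%s order=%d elapsed=%.2fs",
                 s.subject_id, order, time.perf_counter() - t0)
    return pli_list, pdc_list


_fmt_descriptor = format_descriptor


def stage_classify(table: FeatureTable, cfg: PipelineConfig, out: Path,
                   undirected_tag: str = PLI_TAG,
                   directed_tag: str = PDC_TAG) -> dict:
    """Three selection strategies, significance, per-feature comparison."""
    out.mkdir(parents=True, exist_ok=True)
    results = {
        "FC": select_and_classify_single(
            table, undirected_tag, min(cfg.n_max, table.columns_of(undirected_tag).size),
            cfg.positive_class, cfg.svm_c, cfg.rank_on_full_data),
        "EC": select_and_classify_single(
            table, directed_tag, min(cfg.n_max, table.columns_of(directed_tag).size),
            cfg.positive_class, cfg.svm_c, cfg.rank_on_full_data),
        "combined": select_and_classify_combined(
            table, min(cfg.l_max, len(table.descriptors)), cfg.positive_class,
            cfg.svm_c, cfg.rank_on_full_data, undirected_tag, directed_tag),
    }
    best = results["combined"]
    sel_cols = [table.descriptors.index(d) for d in best.selected]
    perm = modified_permutation_test(
        table.values[:, sel_cols], table.labels, cfg.positive_class,
        n_perm=cfg.n_perm_classifier,
        seed=int(np.random.SeedSequence([cfg.seed, 0xCF]).generate_state(1)[0] % 2**31),
        C=cfg.svm_c,
    )
    groups = sorted(set(table.labels.tolist()), key=lambda g: g != cfg.positive_class)
    comparisons = compare_selected_features(
        table.values[:, sel_cols], table.labels, cfg.fdr_q,
        descriptors=best.selected, group_order=(groups[0], groups[1]),
    )
    # performance table (one row per strategy)
    with open(out / "performance.tsv", "w", encoding="utf-8") as fh:
        fh.write("strategy\tacc_pct\tspe_pct\tsen_pct\tauc\tn_features\tsplit\n")
        for name, r in results.items():
            split = f"{r.split[0]}+{r.split[1]}" if r.split else ""
            fh.write(f"{name}\t{r.acc:.2f}\t{r.spe:.2f}\t{r.sen:.2f}\t"
                     f"{r.auc:.3f}\t{r.n_features}\t{split}\n")
    # selected-feature comparison table
    with open(out / "selected_features.tsv", "w", encoding="utf-8") as fh:
        g1, g2 = groups[0], groups[1]
        fh.write(f"feature\t{g1}_mean\t{g1}_sem\t{g2}_mean\t{g2}_sem\t"
                 "direction\tp_raw\tp_fdr\tsignificant\n")
        for c in comparisons:
            m1, s1 = c.mean_sem[g1]
            m2, s2 = c.mean_sem[g2]
            fh.write(f"{_fmt_descriptor(c.descriptor)}\t{m1:.4f}\t{s1:.4f}\t"
                     f"{m2:.4f}\t{s2:.4f}\t{c.direction}\t{c.p_raw:.4g}\t"
                     f"{c.p_fdr:.4g}\t{int(c.significant)}\n")
    summary = {
        "strategies": {
            name: {"acc": r.acc, "spe": r.spe, "sen": r.sen, "auc": r.auc,
                   "n_features": r.n_features,
                   "split": list(r.split) if r.split else None,
                   "selected": [_fmt_descriptor(d) for d in r.selected]}
            for name, r in results.items()
        },
        "permutation_p": perm.p_value,
        "n_perm": perm.n_perm,
    }
    (out / "classification.json").write_text(json.dumps(summary, indent=1),
                                             encoding="utf-8")
    return {"results": results, "permutation": perm,
            "comparisons": comparisons, "summary": summary}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage on the configured manifest; returns the report."""
    if not cfg.manifest:
        raise ValidationError("config must name a subject manifest")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    subjects = load_subjects(cfg.manifest)
    log.info("loaded %d subjects, groups=%s", len(subjects),
             sorted({s.group for s in subjects}))
    tfr = stage_tfr(subjects, cfg, out / "tfr")
    pli_list, pdc_list = stage_connectivity(subjects, cfg, out / "connectivity")
    table = build_feature_table(
        pli_list, pdc_list,
        labels=[s.group for s in subjects],
        subject_ids=[s.subject_id for s in subjects],
    )
    write_feature_table(table, out / "feature_table.tsv")
    clf = stage_classify(table, cfg, out / "classification")
    report = {
        "n_subjects": len(subjects),
        "tf_cluster_test": tfr["summary"],
        "classification": clf["summary"],
    }
    (out / "report.json").write_text(json.dumps(report, indent=1),
                                     encoding="utf-8")
    return report
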