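"""End-to-end orchestration of the proteomics workflow and a full demo.

`run_proteomics_pipeline` executes read -> flag removal -> log2 ->
replicate-presence filter -> (optional imputation) -> prior fit ->
three condition-vs-NES contrasts plus the pairwise Cav1 contrasts ->
enrichment calls -> interactome classification -> z-score profiles,
writing TSV tables and a machine-readable JSON summary whose category
counts mirror the flow-diagram bookkeeping of the experiment.

Every output records the configuration hash and seed; re-running with
the same config reproduces all tables byte-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffenrich, imaging, motility, proteomics, synthdata
from .proteomics import ConfigError, SampleDesign


@dataclass
class RunConfig:
    """Configuration of a proteomics pipeline run."""

    table_path: str
    design_path: str
    out_dir: str = "cavprox_out"
    p_thresh: float = 0.05
    lfc_thresh: float = 0.0
    presence_k: int | None = None  # None = all replicates of a group
    impute: bool = False
    impute_width: float = 0.3
    impute_shift: float = 1.8
    d0_override: float | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for p in (self.table_path, self.design_path):
            if not Path(p).exists():
                raise ConfigError(f"path does not exist: {p}")
        if not 0 < self.p_thresh <= 1:
            raise ConfigError("p_thresh must be in (0, 1]")

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def _provenance(config: RunConfig) -> dict:
    return {"config_hash": config.digest(), "seed": config.seed}


def run_proteomics_pipeline(config: RunConfig) -> dict:
    """Run the full differential-enrichment workflow; returns the summary.

    Validates the design's replicate counts against ``presence_k``
    before any computation; any stage failure aborts with the stage
    name and the row counts accumulated so far.
    """
    config.validate()
    design = SampleDesign.from_csv(config.design_path)
    if config.presence_k is not None:
        for (bait, cond), samples in design.groups().items():
            if config.presence_k > len(samples):
                raise ConfigError(
                    f"presence_k={config.presence_k} exceeds the "
                    f"{len(samples)} replicates of group ({bait}, {cond})"
                )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    stage = "read"
    try:
        table = proteomics.read_protein_table(config.table_path, design)
        log.append(f"read: {len(table)} proteins, {len(design.sample_ids)} samples")

        stage = "remove_flagged_rows"
        table = proteomics.remove_flagged_rows(table)
        log.append(f"remove_flagged_rows: {len(table)} retained")

        stage = "log2_transform"
        logmat = proteomics.log2_transform(table)

        stage = "replicate_presence_filter"
        logmat = proteomics.replicate_presence_filter(logmat, config.presence_k)
        log.append(logmat.provenance[-1])

        if config.impute:
            stage = "impute_downshifted"
            logmat = proteomics.impute_downshifted(
                logmat, config.impute_width, config.impute_shift, config.seed
            )
            log.append(logmat.provenance[-1])

        stage = "fit_variance_prior / contrasts"
        results = diffenrich.nes_contrasts(logmat)
        prior = diffenrich.fit_variance_prior_from_logmat(
            logmat, (("Cav1", "NT"), ("NES", "NT"))
        )
        pairwise = {}
        cav_conditions = [c for b, c in design.groups() if b == "Cav1"]
        for c1, c2 in [("NT", "HYPO"), ("NT", "REC"), ("HYPO", "REC")]:
            if c1 in cav_conditions and c2 in cav_conditions:
                pairwise[f"{c1}_vs_{c2}"] = diffenrich.moderated_t_test(
                    logmat, (("Cav1", c1), ("Cav1", c2))
                )

        stage = "call_enrichment"
        calls = diffenrich.call_enrichment(results, config.p_thresh, config.lfc_thresh)

        stage = "classify_interactome"
        categories, counts = diffenrich.classify_interactome(calls)
        log.append(f"classify_interactome: {counts['total_significant']} significant")

        stage = "zscore_profiles"
        significant = categories.index[categories != "none"]
        zmat = diffenrich.zscore_profiles(logmat, significant, mode="per_sample")
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage {stage!r}; log so far: {log}"
        ) from exc

    prov = _provenance(config)
    for cond, res in {**results, **pairwise}.items():
        res.to_csv(out / f"diff_{cond}.tsv", sep="\t", na_rep="NA")
    calls.to_csv(out / "calls.tsv", sep="\t")
    pd.DataFrame({"category": categories}).to_csv(out / "categories.tsv", sep="\t")
    zmat.to_csv(out / "zscores.tsv", sep="\t", na_rep="NA")
    summary = {
        **prov,
        "stages": log,
        "prior": {"d0": prior.d0, "s0_sq": prior.s0_sq},
        "thresholds": {"p": config.p_thresh, "logFC": config.lfc_thresh},
        "imputation": config.impute,
        "category_counts": counts,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary


def run_demo(out_dir: str | Path, seed: int = 0, plots: bool = True) -> dict:
    """Generate all synthetic fixtures, run every module, write a report.

    Produces the proteomics bundle (tables + volcano/heatmap plots),
    imaging quantifications on planted polarized-cell and PLA images,
    and track statistics with an MSD/Fürth fit. Returns a manifest of
    outputs with the headline numbers.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(seed) % (2**31)

    # --- proteomics ---
    cfg = synthdata.SynthProteomeConfig(seed=rng_seed)
    table, truth = synthdata.simulate_lfq_experiment(cfg)
    table_path = out / "proteinGroups_synthetic.tsv"
    design_path = out / "design.csv"
    proteomics.write_protein_table(table, table_path)
    table.design.to_csv(design_path)
    truth.to_csv(out / "truth.csv")
    summary = run_proteomics_pipeline(
        RunConfig(
            table_path=str(table_path),
            design_path=str(design_path),
            out_dir=str(out / "proteomics"),
            seed=rng_seed,
        )
    )

    # --- imaging ---
    img, mask, img_truth = synthdata.simulate_polarized_cell_image(
        rear_fold=8.0, noise_model="poisson", seed=rng_seed
    )
    axis = imaging.estimate_polarity_axis(mask, img)
    rear, front = imaging.rear_front_halves(mask, axis)
    rli = imaging.rear_localization_index(img, rear, front)
    _, _, quads = imaging.quadrant_profile(img, mask, axis)

    pla_img, pla_mask, pla_truth = synthdata.simulate_pla_image(
        n_dots=12, seed=rng_seed
    )
    counts, dot_mask, centroids = imaging.count_pla_dots(pla_img, pla_mask)
    synthdata.write_image(img, out / "polarized_cell.tif")
    synthdata.write_mask(mask, out / "polarized_cell_mask.tif")
    synthdata.write_image(pla_img, out / "pla.tif")
    synthdata.write_mask(dot_mask.astype(np.uint16), out / "pla_dot_mask.tif")

    # --- motility ---
    track_truth = synthdata.SynthTrackTruth()
    tracks = synthdata.simulate_tracks(100, track_truth, seed=rng_seed)
    tracks = motility.normalize_tracks_to_origin(tracks)
    stats_df = motility.all_track_statistics(tracks)
    curve = motility.msd(tracks, max_lag=int(5 * track_truth.persistence
                                             / track_truth.frame_interval))
    fit = motility.fit_furth(curve)
    synthdata.write_tracks(tracks, out / "tracks.csv")
    stats_df.to_csv(out / "track_stats.csv", index=False)
    curve.to_csv(out / "msd.csv", index=False)

    if plots:
        _demo_plots(out, summary, tracks, curve, fit)

    manifest = {
        "seed": rng_seed,
        "proteomics_summary": summary,
        "imaging": {
            "rear_localization_index": rli,
            "planted_rear_fold": img_truth.rear_fold,
            "quadrant_means_rear_to_front": list(quads),
            "pla_dot_count": int(sum(counts.values())),
            "planted_dot_count": pla_truth.dot_count,
        },
        "motility": {
            "mean_speed_um_per_min": float(stats_df["speed_um_per_min"].mean()),
            "furth_fit": {"S": fit.speed, "P": fit.persistence},
            "planted": {"S": track_truth.speed, "P": track_truth.persistence},
        },
        "files": sorted(str(p.relative_to(out)) for p in out.rglob("*") if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _demo_plots(out: Path, summary: dict, tracks, curve, fit) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    diff = pd.read_csv(out / "proteomics" / "diff_NT.tsv", sep="\t", index_col=0)
    fig, ax = plt.subplots(figsize=(4, 4))
    ok = diff["testable"].fillna(False).astype(bool)
    ax.scatter(diff.loc[ok, "logFC"], -np.log10(diff.loc[ok, "p"]), s=4, alpha=0.4)
    ax.set_xlabel("log2 FC (Cav1-NT vs NES)")
    ax.set_ylabel("-log10 p")
    fig.savefig(out / "volcano_NT.png", dpi=100)
    plt.close(fig)

    z = pd.read_csv(out / "proteomics" / "zscores.tsv", sep="\t", index_col=0)
    fig, ax = plt.subplots(figsize=(4, 6))
    ax.imshow(z.to_numpy(float), aspect="auto", cmap="RdBu_r", vmin=-2, vmax=2)
    ax.set_xticks(range(len(z.columns)))
    ax.set_xticklabels(z.columns, rotation=90, fontsize=5)
    fig.tight_layout()
    fig.savefig(out / "zscore_heatmap.png", dpi=100)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(curve["lag_min"], curve["msd_um2"], "o", ms=3, label="measured")
    ax.plot(
        curve["lag_min"],
        motility.furth_msd(curve["lag_min"].to_numpy(), fit.speed, fit.persistence),
        "-",
        label=f"Fürth fit S={fit.speed:.2f}, P={fit.persistence:.1f}",
    )
    ax.set_xlabel("lag (min)")
    ax.set_ylabel("MSD (µm²)")
    ax.legend(fontsize=7)
    fig.savefig(out / "msd.png", dpi=100)
    plt.close(fig)
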