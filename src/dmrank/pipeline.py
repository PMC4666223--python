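"""End-to-end pipeline: QC -> probe tests -> region calling -> outputs.

Runs the whole analysis for every unordered pair of sample groups and
writes, per pair, a comma-separated region table, BED/bedGraph genome
browser tracks, optional per-region plots and optional gene set
enrichment results into ``<out_dir>/<groupA>_vs_<groupB>/``.  All
outputs are deterministic for a fixed config and seed: rerunning
produces byte-identical files.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .gsea import run_gsea
from .io import MethylationDataset, Region, RegionSet
from .probe_stats import all_pairs_probe_tests
from .region_stats import (
    DEFAULT_LAG_BINS,
    RegionResult,
    call_dmrs,
    results_to_frame,
    sidak_correct_count,
)

__all__ = ["PipelineConfig", "run_pipeline", "write_tracks", "plot_top_regions"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; flags mirror the CLI."""

    matrix_path: str
    sample_sheet_path: str
    regions_path: str  # BED of testing regions
    out_dir: str
    detection_path: str | None = None
    gene_sets_path: str | None = None  # GMT; enables GSEA when set
    normalize: bool = False
    probe_p_cutoff: float = 0.01
    sample_fail_fraction: float = 0.1
    q_cutoff: float = 0.05
    min_abs_median_change: float = 0.0
    lag_bins: tuple[int, ...] = DEFAULT_LAG_BINS
    n_top_plots: int = 0
    gsea_n_perm: int = 1000
    gsea_weight: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.q_cutoff <= 1.0:
            raise ValueError(f"q_cutoff must be in (0, 1], got {self.q_cutoff}")
        paths = {
            "matrix": self.matrix_path,
            "sample sheet": self.sample_sheet_path,
            "regions": self.regions_path,
        }
        if self.detection_path:
            paths["detection matrix"] = self.detection_path
        if self.gene_sets_path:
            paths["gene sets"] = self.gene_sets_path
        for label, p in paths.items():
            if not Path(p).is_file():
                raise FileNotFoundError(f"{label} file missing or unreadable: {p}")


def _probe_changes(ds: MethylationDataset, pair: tuple[str, str]) -> np.ndarray:
    """Per-probe difference of group median betas, second minus first."""
    cols_a = ds.group_columns(pair[0])
    cols_b = ds.group_columns(pair[1])
    return np.median(ds.beta[:, cols_b], axis=1) - np.median(ds.beta[:, cols_a], axis=1)


def _q_to_bed_score(q: float) -> int:
    return min(1000, int(round(-10.0 * math.log10(max(q, 1e-300)))))


def _ramp_color(value: float) -> str:
    """Blue (0) -> red (1) itemRgb ramp."""
    v = min(max(value, 0.0), 1.0)
    return f"{int(round(255 * v))},0,{int(round(255 * (1 - v)))}"


def write_tracks(
    region_results: list[RegionResult],
    ds: MethylationDataset,
    pair: tuple[str, str],
    probe_p_min: np.ndarray,
    out_dir: str | Path,
) -> None:
    """Genome-browser tracks for one group pair.

    Writes (a) significant regions as BED6 with score = round(-10 log10 q)
    capped at 1000 and strand '+' when the second group of the pair is
    the higher-methylated direction; (b) all probes as BED4; (c) probes
    colored by Sidak-corrected per-probe significance (BED9 itemRgb,
    blue = n.s., red = strong); (d) a bedGraph of the per-probe median
    methylation change for bar-plot display.  All sorted, 0-based
    half-open.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    with open(out_dir / "significant_regions.bed", "w") as fh:
        fh.write('track name="significant_regions"\n')
        for r in sorted(region_results, key=lambda r: (r.region.chrom, r.region.start)):
            strand = "+" if r.direction == pair[1] else "-"
            fh.write(
                f"{r.region.chrom}\t{r.region.start}\t{r.region.end}\t"
                f"{r.region.name}\t{_q_to_bed_score(r.q)}\t{strand}\n"
            )

    with open(out_dir / "probes.bed", "w") as fh:
        fh.write('track name="probes"\n')
        for i in range(ds.n_probes):
            fh.write(f"{ds.chrom[i]}\t{ds.pos[i]}\t{ds.pos[i] + 1}\t{ds.probe_ids[i]}\n")

    # per-probe q: the smaller directional p, Sidak-corrected by probe count
    probe_q = np.asarray(
        [sidak_correct_count(p, ds.n_probes) for p in probe_p_min]
    )
    with open(out_dir / "probe_q.bed", "w") as fh:
        fh.write('track name="probe_q" itemRgb="On"\n')
        for i in range(ds.n_probes):
            # ramp position: -log10(q) scaled so q = 1e-5 saturates red
            heat = -math.log10(max(probe_q[i], 1e-300)) / 5.0
            fh.write(
                f"{ds.chrom[i]}\t{ds.pos[i]}\t{ds.pos[i] + 1}\t{ds.probe_ids[i]}\t"
                f"{_q_to_bed_score(probe_q[i])}\t.\t{ds.pos[i]}\t{ds.pos[i] + 1}\t"
                f"{_ramp_color(heat)}\n"
            )

    changes = _probe_changes(ds, pair)
    with open(out_dir / "probe_change.bedgraph", "w") as fh:
        fh.write('track type=bedGraph name="probe_change"\n')
        for i in range(ds.n_probes):
            fh.write(f"{ds.chrom[i]}\t{ds.pos[i]}\t{ds.pos[i] + 1}\t{changes[i]:.6g}\n")


def plot_top_regions(
    region_results: list[RegionResult],
    ds: MethylationDataset,
    k: int,
    out_dir: str | Path,
) -> list[Path]:
    """Group-wise per-probe beta plots for the top-k regions by q."""
    if k <= 0:
        return []
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    probe_index = {p: i for i, p in enumerate(ds.probe_ids)}
    written = []
    top = sorted(region_results, key=lambda r: (r.q, r.region.chrom, r.region.start))
    for rank, r in enumerate(top[:k], start=1):
        idx = [probe_index[p] for p in r.probe_ids]
        fig, ax = plt.subplots(figsize=(6, 3.5))
        for g, marker in zip(r.group_pair, ("o", "s")):
            cols = ds.group_columns(g)
            for j, i in enumerate(idx):
                ax.scatter(
                    [ds.pos[i]] * len(cols), ds.beta[i, cols],
                    marker=marker, alpha=0.6,
                    color="C0" if g == r.group_pair[0] else "C3",
                    label=g if j == 0 else None,
                )
        ax.set_ylim(-0.02, 1.02)
        ax.set_xlabel(f"{r.region.chrom} position (bp)")
        ax.set_ylabel("beta value")
        ax.set_title(f"{r.region.name}  q={r.q:.2e}")
        ax.legend()
        fig.tight_layout()
        path = out_dir / f"region_{rank:02d}_{r.region.name.replace(':', '_').replace('/', '_')}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    return written


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full analysis; returns the output directory.

    Fails fast if any referenced file is missing, then: load and QC the
    data, run all-vs-all probe tests, call regions per group pair, write
    CSV tables and BED tracks, and (when a GMT is configured) run the
    gene set enrichment with leading-edge overlap.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    log_path = out_dir / "run.log"
    lines = ["pipeline configuration:"]
    lines += [f"  {k} = {v}" for k, v in asdict(config).items()]

    ds = dio.read_methylation_matrix(config.matrix_path, config.sample_sheet_path)
    lines.append(f"loaded {ds.n_probes} probes x {ds.n_samples} samples")

    if config.detection_path:
        det_df = pd.read_csv(config.detection_path, sep="\t")
        det = dio.DetectionMatrix(
            probe_ids=det_df["probe_id"].to_numpy(dtype=object),
            samples=[c for c in det_df.columns if c not in ("probe_id", "chrom", "pos")],
            detection_p=det_df[
                [c for c in det_df.columns if c not in ("probe_id", "chrom", "pos")]
            ].to_numpy(dtype=float),
        )
        ds, report = dio.detection_filter(
            ds, det, config.probe_p_cutoff, config.sample_fail_fraction
        )
        lines.append(
            f"detection filter: removed samples {report.removed_samples}, "
            f"{report.n_probes_removed} probes"
        )
    if config.normalize:
        ds = dio.quantile_normalize(ds)
        lines.append("applied quantile normalization")

    regions = dio.read_bed(config.regions_path)
    probe_table = all_pairs_probe_tests(ds)
    calls = call_dmrs(
        ds,
        regions,
        q_cutoff=config.q_cutoff,
        min_abs_median_change=config.min_abs_median_change,
        lag_bins=config.lag_bins,
        probe_table=probe_table,
    )

    for pair, results in calls.items():
        pair_dir = out_dir / f"{pair[0]}_vs_{pair[1]}"
        pair_dir.mkdir(exist_ok=True)
        results_to_frame(results).to_csv(
            pair_dir / "regions.csv", index=False, float_format="%.6g"
        )
        sub = probe_table[
            (probe_table["group_a"] == pair[0]) & (probe_table["group_b"] == pair[1])
        ]
        p_min = np.minimum(
            sub["p_a_greater"].to_numpy(), sub["p_b_greater"].to_numpy()
        )
        write_tracks(results, ds, pair, p_min, pair_dir)
        if config.n_top_plots > 0:
            plot_top_regions(results, ds, config.n_top_plots, pair_dir / "plots")
        lines.append(f"{pair[0]} vs {pair[1]}: {len(results)} significant regions")

        if config.gene_sets_path:
            gene_sets = dio.read_gmt(config.gene_sets_path)
            gene_linked = [r for r in results if r.region.gene_name]
            if gene_linked:
                gsea_results, overlap = run_gsea(
                    gene_linked,
                    gene_sets,
                    weight_p=config.gsea_weight,
                    n_perm=config.gsea_n_perm,
                    seed=config.seed,
                )
                with open(pair_dir / "gsea.tsv", "w") as fh:
                    fh.write("set_name\tsize\tES\tpeak_index\tp_perm\tleading_edge\n")
                    for r in gsea_results:
                        fh.write(
                            f"{r.set_name}\t{r.set_size}\t{r.es:.6g}\t{r.peak_index}\t"
                            f"{r.p_perm:.6g}\t{','.join(r.leading_edge)}\n"
                        )
                overlap.to_csv(pair_dir / "leading_edge_overlap.tsv", sep="\t",
                               float_format="%.6g")
                lines.append(
                    f"{pair[0]} vs {pair[1]}: GSEA on {len(gsea_results)} testable sets"
                )
            else:
                lines.append(
                    f"{pair[0]} vs {pair[1]}: no gene-linked significant region, "
                    "GSEA skipped"
                )

    log_path.write_text("\n".join(lines) + "\n")
    for line in lines:
        logger.info(line)
    return out_dir
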