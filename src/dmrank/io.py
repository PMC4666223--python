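"""Core data containers and plain-text readers/writers.

The pipeline operates on probe-level methylation arrays: a beta-value
matrix (probes x samples, values in [0, 1]) with per-probe genomic
coordinates and per-sample group labels.  All genomic coordinates are
0-based half-open; probe positions are points (width-1 intervals).

Supported formats are deliberately plain text: a TSV methylation matrix
(columns ``probe_id``, ``chrom``, ``pos``, then one column per sample), a
TSV sample sheet (columns ``sample``, ``group``), BED for genomic
regions, GMT for gene sets and a two-column chrom.sizes TSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MethylationDataset",
    "DetectionMatrix",
    "Region",
    "RegionSet",
    "GeneSetCollection",
    "FilterReport",
    "read_methylation_matrix",
    "write_methylation_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "beta_to_m",
    "detection_filter",
    "quantile_normalize",
    "read_bed",
    "write_bed",
    "read_gmt",
    "read_chrom_sizes",
]


@dataclass(frozen=True)
class Region:
    """A genomic interval, 0-based half-open, optionally linked to a gene."""

    chrom: str
    start: int
    end: int
    name: str
    gene_name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"region {self.name}: negative start {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"region {self.name}: start must be < end "
                f"({self.chrom}:{self.start}-{self.end})"
            )

    @property
    def span(self) -> int:
        return self.end - self.start


class RegionSet:
    """An ordered collection of uniquely named regions."""

    def __init__(self, regions: Iterable[Region]):
        self.regions: list[Region] = list(regions)
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate region names: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def __getitem__(self, i):
        return self.regions[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, RegionSet) and self.regions == other.regions

    def sorted(self) -> "RegionSet":
        return RegionSet(sorted(self.regions, key=lambda r: (r.chrom, r.start, r.end)))


@dataclass
class MethylationDataset:
    """Probe x sample beta-value matrix with coordinates and group labels.

    Invariants enforced at construction: betas in [0, 1] with no missing
    values, probes sorted by (chrom, pos), unique probe ids, and every
    sample mapped to exactly one group.
    """

    probe_ids: np.ndarray  # (n_probes,) str
    chrom: np.ndarray  # (n_probes,) str
    pos: np.ndarray  # (n_probes,) int, 0-based point positions
    beta: np.ndarray  # (n_probes, n_samples) float in [0, 1]
    samples: list[str]
    groups: dict[str, str]  # sample -> group label

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.beta = np.asarray(self.beta, dtype=float)
        n_probes = len(self.probe_ids)
        if self.beta.shape != (n_probes, len(self.samples)):
            raise ValueError(
                f"beta shape {self.beta.shape} does not match "
                f"{n_probes} probes x {len(self.samples)} samples"
            )
        if len(set(self.probe_ids)) != n_probes:
            raise ValueError("duplicate probe IDs")
        if np.isnan(self.beta).any():
            raise ValueError(
                "missing beta values are not supported; impute or filter first"
            )
        if (self.beta < 0).any() or (self.beta > 1).any():
            raise ValueError("beta values outside [0, 1]")
        missing = [s for s in self.samples if s not in self.groups]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        # canonical probe order: (chrom, pos)
        order = np.lexsort((self.pos, self.chrom.astype(str)))
        if not np.array_equal(order, np.arange(n_probes)):
            self.probe_ids = self.probe_ids[order]
            self.chrom = self.chrom[order]
            self.pos = self.pos[order]
            self.beta = self.beta[order]

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def group_names(self) -> list[str]:
        return sorted({self.groups[s] for s in self.samples})

    def group_columns(self, group: str) -> np.ndarray:
        """Column indices of the samples belonging to ``group``."""
        idx = [i for i, s in enumerate(self.samples) if self.groups[s] == group]
        if not idx:
            raise KeyError(f"no samples in group {group!r}")
        return np.asarray(idx)

    def require_testable(self) -> None:
        """Raise unless there are >=2 groups with >=2 samples each."""
        sizes = {g: len(self.group_columns(g)) for g in self.group_names()}
        small = {g: n for g, n in sizes.items() if n < 2}
        if len(sizes) < 2:
            raise ValueError("need at least two sample groups for testing")
        if small:
            raise ValueError(f"groups with fewer than 2 samples: {small}")

    def subset_samples(self, keep: Sequence[str]) -> "MethylationDataset":
        idx = [self.samples.index(s) for s in keep]
        return MethylationDataset(
            probe_ids=self.probe_ids.copy(),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            beta=self.beta[:, idx].copy(),
            samples=list(keep),
            groups={s: self.groups[s] for s in keep},
        )

    def subset_probes(self, mask: np.ndarray) -> "MethylationDataset":
        mask = np.asarray(mask, dtype=bool)
        return MethylationDataset(
            probe_ids=self.probe_ids[mask],
            chrom=self.chrom[mask],
            pos=self.pos[mask],
            beta=self.beta[mask],
            samples=list(self.samples),
            groups=dict(self.groups),
        )


@dataclass
class DetectionMatrix:
    """Per-probe, per-sample detection p-values aligned to a dataset."""

    probe_ids: np.ndarray
    samples: list[str]
    detection_p: np.ndarray  # (n_probes, n_samples) in [0, 1]

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.detection_p = np.asarray(self.detection_p, dtype=float)
        if self.detection_p.shape != (len(self.probe_ids), len(self.samples)):
            raise ValueError("detection_p shape mismatch")
        if (self.detection_p < 0).any() or (self.detection_p > 1).any():
            raise ValueError("detection p-values outside [0, 1]")

    def aligned_to(self, ds: MethylationDataset) -> "DetectionMatrix":
        """Reorder to match the probe and sample ordering of ``ds``."""
        probe_idx = {p: i for i, p in enumerate(self.probe_ids)}
        try:
            rows = np.asarray([probe_idx[p] for p in ds.probe_ids])
            cols = np.asarray([self.samples.index(s) for s in ds.samples])
        except (KeyError, ValueError) as exc:
            raise ValueError(f"detection matrix not aligned to dataset: {exc}")
        return DetectionMatrix(
            probe_ids=ds.probe_ids.copy(),
            samples=list(ds.samples),
            detection_p=self.detection_p[np.ix_(rows, cols)],
        )


class GeneSetCollection:
    """Named gene sets with GMT semantics (name, description, members)."""

    def __init__(self, sets: Mapping[str, Sequence[str]]):
        self.sets: dict[str, list[str]] = {}
        for name, members in sets.items():
            deduped = list(dict.fromkeys(members))  # order-preserving dedup
            if not deduped:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = deduped

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


@dataclass
class FilterReport:
    """What the detection-p QC removed."""

    removed_samples: list[str] = field(default_factory=list)
    n_probes_removed: int = 0

    @property
    def empty(self) -> bool:
        return not self.removed_samples and self.n_probes_removed == 0


# ---------------------------------------------------------------------------
# readers / writers


def read_sample_sheet(path: str | Path) -> dict[str, str]:
    """Read a tab-separated sample sheet with columns ``sample``, ``group``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "group"):
        if col not in df.columns:
            raise ValueError(f"sample sheet {path}: missing column {col!r}")
    if df["sample"].duplicated().any():
        dups = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"sample sheet {path}: duplicate samples {dups}")
    return dict(zip(df["sample"], df["group"]))


def write_sample_sheet(groups: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample": list(groups), "group": [groups[s] for s in groups]}
    ).to_csv(path, sep="\t", index=False)


def read_methylation_matrix(
    path: str | Path, sample_sheet_path: str | Path
) -> MethylationDataset:
    """Load a beta-value matrix and its sample sheet into a dataset.

    The matrix is TSV with columns ``probe_id``, ``chrom``, ``pos`` and one
    column per sample.  Every sample named in the sheet must be present in
    the matrix and vice versa; a mismatch is an error rather than a silent
    subset.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = ["probe_id", "chrom", "pos"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"matrix {path}: missing column {col!r}")
    groups = read_sample_sheet(sample_sheet_path)
    matrix_samples = [c for c in df.columns if c not in required]
    missing_in_matrix = sorted(set(groups) - set(matrix_samples))
    if missing_in_matrix:
        raise ValueError(
            f"samples in sheet but not in matrix: {missing_in_matrix}"
        )
    missing_in_sheet = sorted(set(matrix_samples) - set(groups))
    if missing_in_sheet:
        raise ValueError(f"samples in matrix but not in sheet: {missing_in_sheet}")
    return MethylationDataset(
        probe_ids=df["probe_id"].to_numpy(dtype=object),
        chrom=df["chrom"].astype(str).to_numpy(dtype=object),
        pos=df["pos"].to_numpy(dtype=np.int64),
        beta=df[matrix_samples].to_numpy(dtype=float),
        samples=matrix_samples,
        groups=groups,
    )


def write_methylation_matrix(ds: MethylationDataset, path: str | Path) -> None:
    """Write a dataset back to the TSV matrix format, full precision."""
    df = pd.DataFrame({"probe_id": ds.probe_ids, "chrom": ds.chrom, "pos": ds.pos})
    for j, s in enumerate(ds.samples):
        df[s] = ds.beta[:, j]
    df.to_csv(path, sep="\t", index=False)  # default repr round-trips exactly


def beta_to_m(beta, eps: float = 1e-6):
    """Convert beta values to M-values via logit2 with clamping.

    M = log2(b / (1 - b)) with b clamped to [eps, 1 - eps] so that the
    boundary values 0 and 1 map to finite numbers.  Strictly increasing
    in beta and antisymmetric about beta = 0.5.
    """
    if not 0.0 < eps < 0.5:
        raise ValueError(f"eps must be in (0, 0.5), got {eps}")
    b = np.clip(np.asarray(beta, dtype=float), eps, 1.0 - eps)
    out = np.log2(b / (1.0 - b))
    return float(out) if np.isscalar(beta) or out.ndim == 0 else out


def detection_filter(
    ds: MethylationDataset,
    det: DetectionMatrix,
    probe_p_cutoff: float = 0.01,
    sample_fail_fraction: float = 0.1,
) -> tuple[MethylationDataset, FilterReport]:
    """Two-step quality-control filter on detection p-values.

    Step 1 removes whole samples whose fraction of failed probes
    (detection_p > ``probe_p_cutoff``) exceeds ``sample_fail_fraction``.
    Step 2 removes, among the surviving samples, every probe that failed
    in any sample.  Defaults are conventional 450k QC values.
    """
    det = det.aligned_to(ds)
    failed = det.detection_p > probe_p_cutoff  # (probes, samples)
    sample_fail_frac = failed.mean(axis=0)
    bad_samples = [
        s for s, f in zip(ds.samples, sample_fail_frac) if f > sample_fail_fraction
    ]
    keep_samples = [s for s in ds.samples if s not in bad_samples]
    if not keep_samples:
        raise ValueError("detection filter removed every sample")
    keep_cols = [ds.samples.index(s) for s in keep_samples]
    probe_ok = ~failed[:, keep_cols].any(axis=1)
    if not probe_ok.any():
        raise ValueError("detection filter removed every probe")
    out = ds.subset_samples(keep_samples).subset_probes(probe_ok)
    report = FilterReport(
        removed_samples=bad_samples,
        n_probes_removed=int((~probe_ok).sum()),
    )
    return out, report


def quantile_normalize(ds: MethylationDataset) -> MethylationDataset:
    """Cross-sample quantile normalization of the beta matrix.

    Each sample's sorted values are replaced by the across-sample mean of
    sorted values; ties within a sample receive the mean of the reference
    values at their would-be positions.  Output is re-clamped to [0, 1].
    """
    x = ds.beta
    order = np.argsort(x, axis=0, kind="stable")
    ref = np.sort(x, axis=0).mean(axis=1)  # reference distribution
    out = np.empty_like(x)
    ranks = np.empty(x.shape[0], dtype=np.int64)
    for j in range(x.shape[1]):
        ranks[order[:, j]] = np.arange(x.shape[0])
        col = ref[ranks]
        # ties share the mean of the reference values they span
        vals, inv = np.unique(x[:, j], return_inverse=True)
        if len(vals) < x.shape[0]:
            sums = np.bincount(inv, weights=col)
            counts = np.bincount(inv)
            col = (sums / counts)[inv]
        out[:, j] = col
    return MethylationDataset(
        probe_ids=ds.probe_ids.copy(),
        chrom=ds.chrom.copy(),
        pos=ds.pos.copy(),
        beta=np.clip(out, 0.0, 1.0),
        samples=list(ds.samples),
        groups=dict(ds.groups),
    )


def read_bed(path: str | Path) -> RegionSet:
    """Read BED3+ into a RegionSet.

    Column 4 (if present) is the region name; column 7 (if present) is a
    gene_name annotation.  Unnamed records get ``chrom:start-end`` names.
    Track and browser header lines are skipped.
    """
    regions: list[Region] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{line_no}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ValueError(f"{path}:{line_no}: non-numeric coordinates")
            name = (
                fields[3]
                if len(fields) > 3 and fields[3] not in ("", ".")
                else f"{chrom}:{start}-{end}"
            )
            gene = fields[6] if len(fields) > 6 and fields[6] not in ("", ".") else None
            regions.append(Region(chrom, start, end, name, gene))
    return RegionSet(regions)


def write_bed(regions: RegionSet | Iterable[Region], path: str | Path,
              track_name: str | None = None) -> None:
    """Write regions as BED; gene_name (when set) goes to column 7."""
    with open(path, "w") as fh:
        if track_name is not None:
            fh.write(f'track name="{track_name}"\n')
        for r in regions:
            fields = [r.chrom, str(r.start), str(r.end), r.name]
            if r.gene_name is not None:
                fields += ["0", ".", r.gene_name]
            fh.write("\t".join(fields) + "\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read MSigDB-style GMT: name, description, then >=1 member per line."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{line_no}: GMT line needs name, description and "
                    f"at least one member"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{line_no}: duplicate set name {name!r}")
            members = [g for g in fields[2:] if g]
            if not members:
                raise ValueError(f"{path}:{line_no}: set {name!r} has no members")
            sets[name] = members
    return GeneSetCollection(sets)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column chrom.sizes TSV (chrom, length)."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{line_no}: expected chrom<TAB>length")
            length = int(fields[1])
            if length <= 0:
                raise ValueError(f"{path}:{line_no}: non-positive length")
            sizes[fields[0]] = length
    return sizes
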