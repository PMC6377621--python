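"""ARISA electropherogram filtering, binning, and richness.

Peak acceptance follows the fingerprinting convention: a peak is a "true
peak" when it falls inside the group's size window, exceeds an absolute
fluorescence floor, and carries more than a minimum fraction of the summed
fluorescence of all floor-passing peaks in its electropherogram. Accepted
peak counts are the per-sample taxon richness; fragments within one base
pair across samples are merged into shared bins by single linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Electropherogram",
    "PeakTable",
    "BinMap",
    "GROUP_WINDOWS",
    "call_true_peaks",
    "richness",
    "bin_peaks",
    "read_peak_csv",
    "write_peak_csv",
]

#: Fragment-size windows (bp, inclusive) per fingerprinting assay. The total
#: bacterial assay reuses the cyanobacterial window (not stated separately in
#: the source protocol; override via `window=` if needed).
GROUP_WINDOWS: dict[str, tuple[float, float]] = {
    "cyanobacteria": (100.0, 1200.0),
    "fungi": (100.0, 1400.0),
    "bacteria_total": (100.0, 1200.0),
}

RFU_FLOOR = 30.0
RELATIVE_THRESHOLD = 0.003


@dataclass
class Electropherogram:
    """One sample's peak list: fragment sizes (bp) and fluorescence (RFU)."""

    sample_id: str
    sizes: np.ndarray
    rfu: np.ndarray

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=float)
        self.rfu = np.asarray(self.rfu, dtype=float)
        if self.sizes.shape != self.rfu.shape or self.sizes.ndim != 1:
            raise ValueError("sizes and rfu must be matching 1-D arrays")
        if self.sizes.size and np.any(self.sizes < 0):
            raise ValueError(f"negative fragment size in profile {self.sample_id!r}")
        if self.sizes.size and np.any(np.diff(self.sizes) <= 0):
            order = np.argsort(self.sizes, kind="stable")
            self.sizes = self.sizes[order]
            self.rfu = self.rfu[order]
            if np.any(np.diff(self.sizes) == 0):
                raise ValueError(f"duplicate fragment size in profile {self.sample_id!r}")
        if self.rfu.size and np.any(self.rfu < 0):
            raise ValueError(f"negative fluorescence in profile {self.sample_id!r}")

    def __len__(self) -> int:
        return self.sizes.size


@dataclass
class PeakTable:
    """Accepted peaks of one profile with relative fluorescence."""

    sample_id: str
    group: str
    sizes: np.ndarray
    rfu: np.ndarray
    relative_fluorescence: np.ndarray

    def __len__(self) -> int:
        return self.sizes.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "size_bp": self.sizes,
                "rfu": self.rfu,
                "relative_fluorescence": self.relative_fluorescence,
            }
        )


@dataclass
class BinMap:
    """Single-linkage fragment bins: (low, high, bin_id) plus peak assignment."""

    bins: list[tuple[float, float, int]]
    assignment: dict[tuple[str, float], int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.bins)


def call_true_peaks(
    profile: Electropherogram,
    group: str,
    *,
    window: tuple[float, float] | None = None,
    rfu_floor: float = RFU_FLOOR,
    relative_threshold: float = RELATIVE_THRESHOLD,
    relative_mode: str = "fluorescence",
) -> PeakTable:
    """Filter an electropherogram down to its true peaks.

    A peak passes when (a) its size lies inside the group window
    (inclusive), (b) its fluorescence strictly exceeds `rfu_floor`, and
    (c) its fluorescence exceeds `relative_threshold` of the summed
    fluorescence of all peaks above the floor in this profile
    (``relative_mode="fluorescence"``, the default) or of the count of such
    peaks (``relative_mode="count"``).
    """
    if window is None:
        try:
            window = GROUP_WINDOWS[group]
        except KeyError:
            raise ValueError(f"unknown ARISA group {group!r}") from None
    lo, hi = window
    sizes, rfu = profile.sizes, profile.rfu
    over_floor = rfu > rfu_floor
    total = rfu[over_floor].sum()
    if relative_mode == "fluorescence":
        rel = np.divide(rfu, total, out=np.zeros_like(rfu), where=total > 0)
    elif relative_mode == "count":
        # Alternate reading: each peak's share of the floor-passing peak count.
        n_ref = int(over_floor.sum())
        rel = np.full_like(rfu, 1.0 / n_ref) if n_ref else np.zeros_like(rfu)
    else:
        raise ValueError(f"unknown relative_mode {relative_mode!r}")
    keep = (sizes >= lo) & (sizes <= hi) & over_floor & (rel > relative_threshold)
    return PeakTable(
        sample_id=profile.sample_id,
        group=group,
        sizes=sizes[keep],
        rfu=rfu[keep],
        relative_fluorescence=(
            np.divide(rfu[keep], total, out=np.zeros_like(rfu[keep]), where=total > 0)
        ),
    )


def richness(table: PeakTable) -> int:
    """Taxon richness = number of accepted true peaks."""
    return len(table)


def bin_peaks(tables: list[PeakTable], linkage_bp: float = 1.0) -> tuple[BinMap, pd.DataFrame]:
    """Bin accepted peaks across samples and build a community matrix.

    Pooled accepted fragment sizes are clustered by single linkage with a
    `linkage_bp` threshold (fragments within 1 bp chain into one bin). The
    returned community matrix is sites x bins with entries equal to the
    summed relative fluorescence of each sample's peaks in the bin; cast to
    incidence with ``(matrix > 0)``.
    """
    if not tables:
        raise ValueError("no peak tables supplied")
    groups = {t.group for t in tables}
    if len(groups) > 1:
        raise ValueError(f"mixed ARISA groups cannot be binned together: {sorted(groups)}")

    records = []
    for t in tables:
        for s, r in zip(t.sizes, t.relative_fluorescence):
            records.append((t.sample_id, float(s), float(r)))
    sample_ids = [t.sample_id for t in tables]
    if not records:
        return BinMap([]), pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))

    rec = sorted(records, key=lambda x: x[1])
    sizes = np.array([r[1] for r in rec])
    # 1-D single linkage: a new bin starts wherever the gap to the previous
    # pooled size exceeds the threshold; <= threshold chains transitively.
    new_bin = np.ones(len(sizes), dtype=bool)
    new_bin[1:] = np.diff(sizes) > linkage_bp
    bin_id = np.cumsum(new_bin) - 1

    bins: list[tuple[float, float, int]] = []
    for b in range(bin_id.max() + 1):
        members = sizes[bin_id == b]
        bins.append((float(members.min()), float(members.max()), int(b)))
    assignment = {(r[0], r[1]): int(b) for r, b in zip(rec, bin_id)}

    matrix = pd.DataFrame(
        0.0,
        index=pd.Index(sample_ids, name="sample_id"),
        columns=[f"bin_{b:04d}" for b in range(len(bins))],
    )
    for (sid, _, rel), b in zip(rec, bin_id):
        matrix.loc[sid, f"bin_{b:04d}"] += rel
    return BinMap(bins, assignment), matrix


def read_peak_csv(path: str | Path) -> list[Electropherogram]:
    """Read peak-scanner-style CSV (sample_id, size_bp, rfu) into profiles."""
    df = pd.read_csv(path)
    required = {"sample_id", "size_bp", "rfu"}
    if not required.issubset(df.columns):
        raise ValueError(f"peak CSV must have columns {sorted(required)}")
    out = []
    for sid, sub in df.groupby("sample_id", sort=True):
        out.append(Electropherogram(str(sid), sub["size_bp"].to_numpy(), sub["rfu"].to_numpy()))
    return out


def write_peak_csv(profiles: list[Electropherogram], path: str | Path) -> None:
    frames = [
        pd.DataFrame({"sample_id": p.sample_id, "size_bp": p.sizes, "rfu": p.rfu})
        for p in profiles
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
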