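"""Electropherogram peak filtering, binning, and relative abundance.

Raw fragment-analysis peak tables are turned into community fingerprints in
four steps:

1. ``qc_dynamic_range`` — flag profiles whose strongest peak falls outside
   the 2,000–8,000 rfu dynamic range (the sample would be re-run at an
   adjusted concentration).
2. ``filter_peaks`` — drop peaks below the 50 rfu recognition threshold and
   outside the 50–600 bp size window.
3. ``bin_peaks`` — group peaks within a 1.2 bp size window into T-RF bins,
   labeling each bin with the size of its largest-area member.
4. ``abundance_filter`` — drop bins contributing < 1% of total area and
   renormalize the survivors' relative abundances.

Replicate runs of the same digestion mixture are merged with
``consensus_profile``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .digest import FAM, HEX

#: canonical column order of a binned-profile table
BIN_COLUMNS = ["dye", "size_bp", "area", "rel_abundance"]


@dataclass(frozen=True)
class Peak:
    """One size-called fluorescence peak."""

    size_bp: float
    height_rfu: float
    area: float
    dye: str

    def __post_init__(self) -> None:
        if self.size_bp <= 0:
            raise ValueError("size_bp must be positive")
        if self.height_rfu < 0 or self.area < 0:
            raise ValueError("height and area must be nonnegative")


@dataclass
class PeakProfile:
    """All peaks of one electropherogram run, sorted by (dye, size)."""

    sample_id: str
    peaks: list[Peak]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: (p.dye, p.size_bp))

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class BinnedProfile:
    """T-RF bins with summed areas — the community fingerprint.

    ``bins`` has columns dye, size_bp (representative size), area,
    rel_abundance.
    """

    sample_id: str
    bins: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bins = (self.bins[BIN_COLUMNS]
                     .sort_values(["dye", "size_bp"], kind="mergesort")
                     .reset_index(drop=True))

    def channel(self, dye: str) -> pd.DataFrame:
        return self.bins[self.bins["dye"] == dye]

    def abundances(self, dye: str | None = None) -> np.ndarray:
        """Relative abundances, renormalized within one dye channel when
        ``dye`` is given."""
        sub = self.bins if dye is None else self.channel(dye)
        a = sub["rel_abundance"].to_numpy(float)
        total = a.sum()
        if total <= 0:
            raise ValueError("empty profile")
        return a / total


def qc_dynamic_range(profile: PeakProfile,
                     fluorescence_range: tuple[float, float] = (2000.0, 8000.0)) -> str:
    """``"pass"`` if the strongest peak height lies inside the dynamic range
    (bounds inclusive), ``"rerun"`` otherwise."""
    if not profile.peaks:
        raise ValueError("no peaks")
    lo, hi = fluorescence_range
    strongest = max(p.height_rfu for p in profile.peaks)
    return "pass" if lo <= strongest <= hi else "rerun"


def filter_peaks(profile: PeakProfile, amplitude_threshold: float = 50.0,
                 min_size: float = 50.0, max_size: float = 600.0) -> PeakProfile:
    """Retain peaks with height >= threshold and size inside [min, max]."""
    if amplitude_threshold <= 0 or min_size <= 0 or max_size <= 0:
        raise ValueError("thresholds must be positive")
    kept = [p for p in profile.peaks
            if p.height_rfu >= amplitude_threshold and min_size <= p.size_bp <= max_size]
    return PeakProfile(profile.sample_id, kept, dict(profile.metadata))


def _greedy_bins(sizes: np.ndarray, areas: np.ndarray,
                 window: float) -> list[tuple[float, float]]:
    """Greedy window binning of one dye channel.

    Repeatedly seed a bin at the largest-area unassigned peak (area ties
    broken toward the smaller size) and absorb every unassigned peak within
    ``window`` bp of the seed.  The seed is by construction the largest-area
    member, so it is also the bin's representative size.  Returns
    (representative_size, total_area) pairs.
    """
    order = np.lexsort((sizes, -areas))  # area desc, then size asc
    unassigned = np.ones(len(sizes), dtype=bool)
    out = []
    for i in order:
        if not unassigned[i]:
            continue
        members = unassigned & (np.abs(sizes - sizes[i]) <= window)
        out.append((float(sizes[i]), float(areas[members].sum())))
        unassigned &= ~members
    return out


def bin_peaks(profile: PeakProfile, bin_window: float = 1.2) -> BinnedProfile:
    """Group peaks of each dye channel into T-RF bins.

    A bin is seeded at the largest-area unassigned peak and absorbs every
    peak within ``bin_window`` bp of the seed; the representative size is
    the seed's (the maximum-area member).  Relative abundance here is
    area / grand total over both channels, before the 1% filter.
    """
    rows = []
    for dye in sorted({p.dye for p in profile.peaks}):
        chan = [p for p in profile.peaks if p.dye == dye]
        sizes = np.array([p.size_bp for p in chan])
        areas = np.array([p.area for p in chan])
        for size, area in _greedy_bins(sizes, areas, bin_window):
            rows.append({"dye": dye, "size_bp": size, "area": area})
    bins = pd.DataFrame(rows, columns=["dye", "size_bp", "area"])
    total = bins["area"].sum()
    bins["rel_abundance"] = bins["area"] / total if total > 0 else 0.0
    return BinnedProfile(profile.sample_id, bins, dict(profile.metadata))


def abundance_filter(binned: BinnedProfile, min_fraction: float = 0.01) -> BinnedProfile:
    """Drop bins contributing strictly less than ``min_fraction`` of the
    grand total area (both dyes), then recompute relative abundances over
    the survivors so they sum to 1."""
    total = binned.bins["area"].sum()
    if total <= 0:
        raise ValueError("total area must be positive")
    keep = binned.bins["area"] / total >= min_fraction
    if not keep.any():
        raise ValueError("empty profile after filtering")
    bins = binned.bins.loc[keep].copy()
    bins["rel_abundance"] = bins["area"] / bins["area"].sum()
    return BinnedProfile(binned.sample_id, bins, dict(binned.metadata))


def consensus_profile(replicates: Sequence[BinnedProfile],
                      match_window: float = 1.2) -> BinnedProfile:
    """Average replicate fingerprints of the same sample.

    Bin representatives from all replicates are pooled and re-binned with
    the same greedy window algorithm; matched areas are averaged over the
    number of replicates (a bin absent from a replicate contributes 0), and
    relative abundances renormalized.  With one replicate this is the
    identity; identical replicates return themselves.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    n = len(replicates)
    pooled = pd.concat([r.bins for r in replicates], ignore_index=True)
    rows = []
    for dye, chan in pooled.groupby("dye", sort=True):
        sizes = chan["size_bp"].to_numpy(float)
        areas = chan["area"].to_numpy(float)
        for size, area in _greedy_bins(sizes, areas, match_window):
            rows.append({"dye": dye, "size_bp": size, "area": area / n})
    bins = pd.DataFrame(rows, columns=["dye", "size_bp", "area"])
    bins["rel_abundance"] = bins["area"] / bins["area"].sum()
    sample_id = replicates[0].sample_id
    meta = dict(replicates[0].metadata)
    meta["n_replicates"] = n
    return BinnedProfile(sample_id, bins, meta)
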