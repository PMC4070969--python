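"""In-silico restriction digestion and T-RF assignment.

Terminal restriction fragment length polymorphism (T-RFLP) sizes only the
fluorescently labeled *terminal* fragment of each amplicon: the stretch from
the labeled 5' end to the first restriction cut.  With double-end labeling
(HEX on the forward primer, FAM on the reverse primer) every amplicon yields
two terminal fragments, one per dye channel.  This module predicts those
fragment lengths from sequence, derives full-digest RFLP patterns for clone
typing, and matches observed electropherogram bins back to predicted
fragments within a size tolerance.

The default enzyme is HinfI, recognition site ``GANTC`` cut after the first
base (``G^ANTC``).  The recognition site is degenerate and palindromic with
respect to its IUPAC class, so forward- and reverse-strand sites coincide.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

HEX = "HEX"
FAM = "FAM"

#: IUPAC nucleotide codes -> the set of bases each matches.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _motif_regex(recognition: str) -> re.Pattern:
    parts = []
    for code in recognition.upper():
        bases = IUPAC.get(code)
        if bases is None:
            raise ValueError(f"not an IUPAC code: {code!r}")
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    # lookahead so overlapping occurrences are all reported
    return re.compile("(?=" + "".join(parts) + ")")


@dataclass(frozen=True)
class AmpliconSequence:
    """A single amplicon: id plus bases over A/C/G/T, labeled 5'->3'."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError("empty sequence")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class PredictedTRF:
    """Predicted terminal fragments of one phylotype, after dye correction.

    ``forward_trf_bp`` is the apparent size of the HEX-labeled fragment
    (5' end of the forward strand to the first cut), ``reverse_trf_bp``
    the FAM-labeled fragment measured on the reverse complement.  Dye
    offsets model the mobility difference between HEX- and FAM-labeled
    molecules; apparent size = true length + offset.
    """

    phylotype_id: str
    forward_trf_bp: float
    reverse_trf_bp: float
    hex_offset: float = 0.0
    fam_offset: float = 0.0

    @property
    def forward_length(self) -> float:
        """Uncorrected forward fragment length in bp."""
        return self.forward_trf_bp - self.hex_offset

    @property
    def reverse_length(self) -> float:
        return self.reverse_trf_bp - self.fam_offset


def find_sites(seq: AmpliconSequence | str, recognition: str = "GANTC",
               cut_offset: int = 1) -> list[int]:
    """0-based start positions of every recognition-site match.

    The enzyme cuts after position ``start + cut_offset - 1``, i.e. the
    fragment boundary sits at index ``start + cut_offset``.
    """
    bases = seq.bases if isinstance(seq, AmpliconSequence) else seq
    if not 0 < cut_offset <= len(recognition):
        raise ValueError("cut_offset must lie within the motif")
    return [m.start() for m in _motif_regex(recognition).finditer(bases.upper())]


def _cut_points(bases: str, recognition: str, cut_offset: int) -> list[int]:
    return [p + cut_offset for p in find_sites(bases, recognition, cut_offset)]


def predict_trf(seq: AmpliconSequence, dye_offsets: tuple[float, float] = (0.0, 0.0),
                recognition: str = "GANTC", cut_offset: int = 1) -> PredictedTRF:
    """Terminal fragment lengths for a double-end-labeled amplicon.

    Forward fragment: labeled 5' end of the given strand to the first cut
    (the full amplicon length when the sequence is uncut).  The reverse
    fragment is computed identically on the reverse complement.
    """
    hex_off, fam_off = dye_offsets
    fwd_cuts = _cut_points(seq.bases, recognition, cut_offset)
    rev_cuts = _cut_points(reverse_complement(seq.bases), recognition, cut_offset)
    fwd = fwd_cuts[0] if fwd_cuts else len(seq)
    rev = rev_cuts[0] if rev_cuts else len(seq)
    return PredictedTRF(seq.id, fwd + hex_off, rev + fam_off,
                        hex_offset=hex_off, fam_offset=fam_off)


def rflp_pattern(seq: AmpliconSequence, recognition: str = "GANTC",
                 cut_offset: int = 1) -> tuple[int, ...]:
    """Sorted fragment-length multiset of a complete digest.

    Fragment lengths always sum to the amplicon length.
    """
    cuts = _cut_points(seq.bases, recognition, cut_offset)
    bounds = [0, *cuts, len(seq)]
    return tuple(sorted(b - a for a, b in zip(bounds, bounds[1:])))


@dataclass
class CloneLibrary:
    """Clone counts per RFLP pattern (a pattern = one phylotype/OTU)."""

    counts: dict[tuple[int, ...], int]
    metadata: dict = field(default_factory=dict)

    @property
    def n_clones(self) -> int:
        return sum(self.counts.values())

    def count_vector(self) -> np.ndarray:
        return np.array(sorted(self.counts.values(), reverse=True), dtype=int)


def cluster_patterns(patterns: Sequence[tuple[int, ...]],
                     fragment_tolerance: float = 0.0) -> pd.DataFrame:
    """Merge RFLP patterns that agree fragment-by-fragment within a tolerance.

    Patterns with different fragment counts never merge.  Clustering is
    greedy against the first representative of each OTU, in input order,
    which is deterministic and exact equality-partitioning at tolerance 0.

    Returns a DataFrame with one row per input pattern: ``pattern``,
    ``otu_id`` and, joined over the whole input, ``otu_size``.
    """
    if fragment_tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    reps: list[tuple[int, ...]] = []
    assignment: list[int] = []
    for pat in patterns:
        pat = tuple(sorted(pat))
        hit = None
        for i, rep in enumerate(reps):
            if len(rep) == len(pat) and all(
                    abs(a - b) <= fragment_tolerance for a, b in zip(rep, pat)):
                hit = i
                break
        if hit is None:
            reps.append(pat)
            hit = len(reps) - 1
        assignment.append(hit)
    out = pd.DataFrame({
        "pattern": [tuple(sorted(p)) for p in patterns],
        "otu_id": [f"OTU{i + 1:02d}" for i in assignment],
    })
    sizes = out["otu_id"].value_counts()
    out["otu_size"] = out["otu_id"].map(sizes)
    return out


UNASSIGNED = "unassigned"


def _pool_predictions(predictions: Sequence[PredictedTRF]) -> dict[str, list[tuple[float, str]]]:
    """Per-dye (size, label) lists; phylotypes sharing an identical predicted
    size are pooled under a joined label (``"P1+P2"``)."""
    per_dye: dict[str, list[tuple[float, str]]] = {HEX: [], FAM: []}
    for dye in (HEX, FAM):
        sizes: dict[float, list[str]] = {}
        for p in predictions:
            size = p.forward_trf_bp if dye == HEX else p.reverse_trf_bp
            sizes.setdefault(size, []).append(p.phylotype_id)
        per_dye[dye] = sorted((s, "+".join(sorted(ids))) for s, ids in sizes.items())
    return per_dye


def assign_trfs(binned, predictions: Sequence[PredictedTRF],
                tolerance: float = 2.0, require_both_dyes: bool = False) -> pd.DataFrame:
    """Match observed T-RF bins to predicted fragments of the same dye.

    Each bin is assigned to the nearest predicted fragment within
    ``tolerance`` bp; exact distance ties go to the smaller predicted size.
    Phylotypes predicted at the same size are pooled into one signal.  Bins
    with no prediction in range are labeled ``"unassigned"``.  When
    ``require_both_dyes`` is set, assignments to phylotypes whose other-dye
    fragment is absent from the profile are demoted to unassigned.
    """
    if not predictions:
        raise ValueError("predictions must be nonempty")
    pooled = _pool_predictions(predictions)
    rows = []
    for _, bin_row in binned.bins.iterrows():
        dye = bin_row["dye"]
        size = bin_row["size_bp"]
        best_label, best_pred, best_delta = UNASSIGNED, np.nan, np.nan
        for pred_size, label in pooled.get(dye, []):
            delta = abs(size - pred_size)
            if delta <= tolerance and (np.isnan(best_delta) or delta < best_delta):
                # list is size-sorted, so strict < keeps the smaller size on ties
                best_label, best_pred, best_delta = label, pred_size, delta
        rows.append({
            "sample_id": binned.sample_id, "dye": dye, "size_bp": size,
            "area": bin_row["area"], "rel_abundance": bin_row["rel_abundance"],
            "assigned_to": best_label, "predicted_size_bp": best_pred,
            "delta_bp": best_delta,
        })
    table = pd.DataFrame(rows)
    if require_both_dyes and len(table):
        matched = {dye: set(table.loc[(table["dye"] == dye)
                                      & (table["assigned_to"] != UNASSIGNED),
                                      "assigned_to"]) for dye in (HEX, FAM)}
        both = matched[HEX] & matched[FAM]
        demote = (table["assigned_to"] != UNASSIGNED) & ~table["assigned_to"].isin(both)
        table.loc[demote, ["assigned_to", "predicted_size_bp", "delta_bp"]] = \
            [UNASSIGNED, np.nan, np.nan]
    return table


def phylotypes_present(assignment: pd.DataFrame) -> set[str]:
    """Phylotype labels (pooled labels split apart) with >= 1 assigned bin."""
    present: set[str] = set()
    for label in assignment.loc[assignment["assigned_to"] != UNASSIGNED, "assigned_to"]:
        present.update(label.split("+"))
    return present


def estimate_abundances(assignment: pd.DataFrame) -> pd.Series:
    """Relative abundance per (possibly pooled) phylotype signal.

    Within each dye channel the assigned bins' relative areas are summed per
    label and renormalized over assigned signal only (spurious/unassigned
    mass is discarded); the two channel estimates are then averaged.  On a
    noiseless profile both channels give the ground-truth proportions.
    """
    assigned = assignment[assignment["assigned_to"] != UNASSIGNED]
    if assigned.empty:
        raise ValueError("no assigned bins")
    per_dye = []
    for dye, sub in assigned.groupby("dye"):
        s = sub.groupby("assigned_to")["rel_abundance"].sum()
        per_dye.append(s / s.sum())
    est = pd.concat(per_dye, axis=1).fillna(0.0).mean(axis=1)
    est = est / est.sum()
    est.index.name = "phylotype"
    return est.sort_index()
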