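"""Readers and writers for the plain-text interchange formats.

* peak tables — CSV with columns sample_id, dye, size_bp, height_rfu, area
  (the dialect exported by fragment-analysis software);
* binned profiles — TSV with sample_id, dye, size_bp, area, rel_abundance;
* sequences — FASTA (via Biopython);
* clone libraries — TSV with pattern (comma-joined fragment lengths) and
  count;
* ground truth / run manifests — JSON with sorted keys.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .digest import AmpliconSequence, CloneLibrary
from .peaks import BinnedProfile, Peak, PeakProfile

PEAK_COLUMNS = ["sample_id", "dye", "size_bp", "height_rfu", "area"]
PROFILE_COLUMNS = ["sample_id", "dye", "size_bp", "area", "rel_abundance"]


def write_peak_csv(profiles: Sequence[PeakProfile], path) -> None:
    rows = [{"sample_id": p.sample_id, "dye": pk.dye, "size_bp": pk.size_bp,
             "height_rfu": pk.height_rfu, "area": pk.area}
            for p in profiles for pk in p.peaks]
    pd.DataFrame(rows, columns=PEAK_COLUMNS).to_csv(path, index=False)


def read_peak_csv(path, metadata: dict | None = None) -> list[PeakProfile]:
    df = pd.read_csv(path)
    missing = set(PEAK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    meta_by_sample = metadata or {}
    profiles = []
    for sample_id, sub in df.groupby("sample_id", sort=True):
        peaks = [Peak(float(r.size_bp), float(r.height_rfu), float(r.area),
                      str(r.dye)) for r in sub.itertuples()]
        profiles.append(PeakProfile(str(sample_id), peaks,
                                    dict(meta_by_sample.get(sample_id, {}))))
    return profiles


def write_profile_tsv(profiles: Sequence[BinnedProfile], path) -> None:
    frames = []
    for p in profiles:
        b = p.bins.copy()
        b.insert(0, "sample_id", p.sample_id)
        frames.append(b)
    out = pd.concat(frames, ignore_index=True) if frames else \
        pd.DataFrame(columns=PROFILE_COLUMNS)
    out[PROFILE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_profile_tsv(path) -> list[BinnedProfile]:
    df = pd.read_csv(path, sep="\t")
    return [BinnedProfile(str(sid), sub.drop(columns="sample_id"))
            for sid, sub in df.groupby("sample_id", sort=True)]


def write_fasta(sequences: Iterable[AmpliconSequence], path) -> None:
    records = [SeqRecord(Seq(s.bases), id=s.id, description="")
               for s in sequences]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[AmpliconSequence]:
    return [AmpliconSequence(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]


def write_clone_library_tsv(library: CloneLibrary, path) -> None:
    rows = [{"pattern": ",".join(map(str, pat)), "count": count}
            for pat, count in sorted(library.counts.items())]
    pd.DataFrame(rows, columns=["pattern", "count"]).to_csv(
        path, sep="\t", index=False)


def read_clone_library_tsv(path) -> CloneLibrary:
    df = pd.read_csv(path, sep="\t")
    counts = {tuple(int(x) for x in str(r.pattern).split(",")): int(r.count)
              for r in df.itertuples()}
    return CloneLibrary(counts)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
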