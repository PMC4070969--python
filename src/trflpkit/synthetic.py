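"""Ground-truth community and electropherogram simulation.

Generates the inputs the analysis chain consumes, with known ground truth:

* a community of phylotypes with known relative abundances and ~800 bp
  SSU amplicon sequences carrying the AMF-specific primer sites (AML1
  forward, AML2 reverse) and engineered HinfI (GANTC) sites;
* replicate electropherogram peak tables (HEX = forward-labeled T-RFs,
  FAM = reverse-labeled) with size-call jitter, replicate area noise, and
  spurious low-area peaks;
* multinomially sampled clone libraries typed by RFLP pattern.

Sequences are built constructively: the forward terminal fragment length f
is set by injecting a GANTC site starting at position f-1, and the reverse
fragment length r by a second site at position L-4-r (GANTC matches its own
reverse complement as a degenerate class, so one site serves both strands).
Background bases are uniform over A/C/G/T with any accidental GANTC match
mutated away, which guarantees the injected sites are the first cut on each
strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .digest import (AmpliconSequence, CloneLibrary, FAM, HEX, IUPAC,
                     predict_trf, reverse_complement, rflp_pattern)
from .peaks import Peak, PeakProfile

#: AMF-specific 18S rRNA gene primers (forward AML1, reverse AML2).
AML1 = "ATCAACTTTCGATGGTAGGATAGA"
AML2 = "GAACCCAAACACTTTGGTTTCC"

HINFI_SITE = "GANTC"
#: constant peak width (bp) relating area and height: height = area / width
PEAK_WIDTH = 1.0
#: size window (bp) inside which T-RFs are placed and later analyzed
SIZE_WINDOW = (50, 600)
DEFAULT_AMPLICON_LENGTH = 800


@dataclass(frozen=True)
class GroundTruthCommunity:
    """Known community: phylotype labels, proportions, amplicon sequences."""

    phylotype_ids: tuple[str, ...]
    abundances: tuple[float, ...]
    sequences: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        a = np.asarray(self.abundances, float)
        if (a < 0).any() or abs(a.sum() - 1.0) > 1e-9:
            raise ValueError("abundances must be nonnegative and sum to 1")
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("sequences must be distinct")

    @property
    def n_phylotypes(self) -> int:
        return len(self.phylotype_ids)

    def amplicons(self) -> list[AmpliconSequence]:
        return [AmpliconSequence(pid, seq)
                for pid, seq in zip(self.phylotype_ids, self.sequences)]

    def predicted_trfs(self, dye_offsets: tuple[float, float] = (0.0, 0.0)) -> list:
        return [predict_trf(a, dye_offsets) for a in self.amplicons()]


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise parameters of the simulated electropherograms.

    size_jitter_sd        size-call error SD in bp
    spurious_peak_rate    expected spurious peaks per profile (Poisson)
    area_cv               coefficient of variation of a peak's area across
                          replicate runs (multiplicative gamma noise)
    total_fluorescence_range
                          (low, high) rfu: the strongest simulated peak
                          height is scaled into this range, matching the
                          dynamic-range QC target
    """

    size_jitter_sd: float = 0.15
    spurious_peak_rate: float = 2.0
    area_cv: float = 0.05
    total_fluorescence_range: tuple[float, float] = (2000.0, 8000.0)

    def __post_init__(self) -> None:
        if min(self.size_jitter_sd, self.spurious_peak_rate, self.area_cv) < 0:
            raise ValueError("noise parameters must be nonnegative")
        if not 0 < self.total_fluorescence_range[0] <= self.total_fluorescence_range[1]:
            raise ValueError("invalid fluorescence range")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(size_jitter_sd=0.0, spurious_peak_rate=0.0, area_cv=0.0)


def _matches_at(bases: list[str], pos: int, motif: str = HINFI_SITE) -> bool:
    if pos < 0 or pos + len(motif) > len(bases):
        return False
    return all(bases[pos + k] in IUPAC[c] for k, c in enumerate(motif))


def _scrub_sites(bases: list[str], protected: list[tuple[int, int]],
                 allowed_starts: set[int], rng: np.random.Generator,
                 motif: str = HINFI_SITE) -> None:
    """Mutate away every motif match whose start is not in allowed_starts.

    For each spurious match, one unprotected base at a non-degenerate motif
    offset is changed to a base that breaks the match.  Rescans until clean.
    """
    def is_protected(i: int) -> bool:
        return any(lo <= i < hi for lo, hi in protected)

    for _ in range(10_000):
        dirty = [p for p in range(len(bases) - len(motif) + 1)
                 if p not in allowed_starts and _matches_at(bases, p, motif)]
        if not dirty:
            return
        p = dirty[0]
        for k, code in enumerate(motif):
            options = IUPAC[code]
            if len(options) == 4 or is_protected(p + k):
                continue  # N offsets cannot break a match
            bad = set(options)
            bases[p + k] = rng.permutation([b for b in "ACGT" if b not in bad])[0]
            break
        else:  # pragma: no cover - geometry prevents this
            raise RuntimeError("cannot scrub recognition site")
    raise RuntimeError("site scrubbing did not converge")  # pragma: no cover


def _spaced_draw(n: int, low: int, high: int, gap: int,
                 rng: np.random.Generator) -> np.ndarray:
    """n sorted integers in [low, high] with pairwise gaps >= gap."""
    slack = (high - low) - (n - 1) * gap
    if slack < 0:
        raise ValueError("cannot place fragments: separation too large for "
                         f"{n} phylotypes in [{low}, {high}]")
    u = np.sort(rng.integers(0, slack + 1, size=n))
    return low + u + gap * np.arange(n)


def _build_sequence(f: int, r: int, length: int, rng: np.random.Generator) -> str:
    """One amplicon whose first forward cut gives a T-RF of f bp and first
    reverse-strand cut gives r bp."""
    bases = list("".join(rng.choice(list("ACGT"), size=length)))
    tail = reverse_complement(AML2)
    bases[:len(AML1)] = AML1
    bases[length - len(tail):] = tail
    p1, p2 = f - 1, length - 4 - r
    for p in (p1, p2):
        site = list(HINFI_SITE)
        site[2] = rng.permutation(list("ACGT"))[0]  # the N position
        bases[p:p + 5] = site
    protected = [(0, len(AML1)), (length - len(tail), length),
                 (p1, p1 + 5), (p2, p2 + 5)]
    _scrub_sites(bases, protected, {p1, p2}, rng)
    return "".join(bases)


def generate_community(n_phylotypes: int, concentration: float = 1.0,
                       min_trf_separation: float = 4.0, seed: int = 0,
                       amplicon_length: int = DEFAULT_AMPLICON_LENGTH,
                       abundances: "tuple[float, ...] | None" = None,
                       ) -> GroundTruthCommunity:
    """Random ground-truth community with controlled T-RF spacing.

    Forward T-RFs (and reverse T-RFs) of distinct phylotypes are placed in
    the 50–600 bp window with pairwise gaps strictly greater than
    ``min_trf_separation``.  Abundances are a symmetric Dirichlet draw with
    the given concentration unless explicit proportions are supplied.
    Raises ``ValueError("cannot place fragments...")`` when the requested
    separation cannot fit.
    """
    if n_phylotypes < 1:
        raise ValueError("n_phylotypes must be >= 1")
    if min_trf_separation < 0:
        raise ValueError("min_trf_separation must be >= 0")
    rng = np.random.default_rng(seed)
    gap = int(np.floor(min_trf_separation)) + 1
    low, high = SIZE_WINDOW
    fwd = _spaced_draw(n_phylotypes, low, high, gap, rng)
    # reverse T-RFs additionally need f + r <= L - 12 so the two engineered
    # sites stay disjoint; pair large f with small r (sorted descending)
    rev_high = min(high, amplicon_length - 12 - int(fwd.max()))
    rev = _spaced_draw(n_phylotypes, low, rev_high, gap, rng)[::-1]
    if np.any(fwd + rev > amplicon_length - 12):
        raise ValueError("cannot place fragments: forward/reverse T-RFs "
                         "exceed the amplicon length")
    order = rng.permutation(n_phylotypes)
    fwd, rev = fwd[order], rev[order]
    sequences = tuple(_build_sequence(int(f), int(r), amplicon_length, rng)
                      for f, r in zip(fwd, rev))
    if abundances is None:
        ab = rng.dirichlet(np.full(n_phylotypes, float(concentration)))
        ab = ab / ab.sum()
    else:
        ab = np.asarray(abundances, float)
        if len(ab) != n_phylotypes:
            raise ValueError("abundances length must equal n_phylotypes")
    ids = tuple(f"P{i + 1:02d}" for i in range(n_phylotypes))
    return GroundTruthCommunity(ids, tuple(float(x) for x in ab), sequences, seed)


def simulate_profiles(community: GroundTruthCommunity, noise: NoiseModel,
                      n_replicates: int = 3, seed: int = 0,
                      sample_id: str = "sample", metadata: dict | None = None,
                      dye_offsets: tuple[float, float] = (0.0, 0.0),
                      ) -> list[PeakProfile]:
    """Replicate electropherograms of one digestion mixture.

    Each replicate holds one HEX peak per phylotype at its forward T-RF and
    one FAM peak at its reverse T-RF, sizes jittered by
    Normal(0, size_jitter_sd), areas proportional to abundance with
    multiplicative gamma noise of the given CV, scaled so the strongest
    peak height lands in the dynamic range.  Poisson(spurious_peak_rate)
    noise peaks are added uniformly over the size window with areas uniform
    in (0, 2% of total signal).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    preds = community.predicted_trfs(dye_offsets)
    truth = {HEX: np.array([p.forward_trf_bp for p in preds], float),
             FAM: np.array([p.reverse_trf_bp for p in preds], float)}
    ab = np.asarray(community.abundances, float)
    lo, hi = noise.total_fluorescence_range
    profiles = []
    for r in range(n_replicates):
        target_max = rng.uniform(lo, hi)
        areas = {}
        for dye in (HEX, FAM):
            if noise.area_cv > 0:
                shape = 1.0 / noise.area_cv ** 2
                factors = rng.gamma(shape, 1.0 / shape, size=len(ab))
            else:
                factors = np.ones(len(ab))
            areas[dye] = ab * factors
        peak_max = max(areas[HEX].max(), areas[FAM].max()) / PEAK_WIDTH
        scale = target_max / peak_max
        peaks = []
        for dye in (HEX, FAM):
            jit = (rng.normal(0.0, noise.size_jitter_sd, size=len(ab))
                   if noise.size_jitter_sd > 0 else np.zeros(len(ab)))
            for size, area in zip(truth[dye] + jit, areas[dye] * scale):
                peaks.append(Peak(float(size), float(area) / PEAK_WIDTH,
                                  float(area), dye))
        total_signal = sum(p.area for p in peaks)
        n_spurious = rng.poisson(noise.spurious_peak_rate)
        for _ in range(n_spurious):
            size = rng.uniform(*SIZE_WINDOW)
            area = rng.uniform(0.0, 0.02 * total_signal)
            dye = HEX if rng.random() < 0.5 else FAM
            peaks.append(Peak(float(size), area / PEAK_WIDTH, area, dye))
        meta = dict(metadata or {})
        meta["replicate"] = r + 1
        profiles.append(PeakProfile(f"{sample_id}-r{r + 1}", peaks, meta))
    return profiles


def sample_clone_library(community: GroundTruthCommunity, n_clones: int = 96,
                         seed: int = 0, metadata: dict | None = None) -> CloneLibrary:
    """Multinomial clone picking typed by in-silico RFLP pattern.

    Draws ``n_clones`` clones with phylotype probabilities equal to the
    ground-truth abundances; counts are keyed by each phylotype's full-
    digest fragment multiset (phylotypes with identical patterns merge).
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n_clones, np.asarray(community.abundances, float))
    counts: dict[tuple[int, ...], int] = {}
    for amp, k in zip(community.amplicons(), draws):
        if k > 0:
            pat = rflp_pattern(amp)
            counts[pat] = counts.get(pat, 0) + int(k)
    meta = dict(metadata or {})
    meta["n_clones"] = n_clones
    return CloneLibrary(counts, meta)
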