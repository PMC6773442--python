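"""Synthetic DNA substrates for unwinding assays.

Hairpin substrates mimic the magnetic-tweezers constructs: a duplex stem that
the helicase opens base pair by base pair, read 5'->3' on the tracking strand,
with optional GC-rich clusters planted at chosen positions so that duplex
stability peaks (and hence pause sites) sit where the experiment design wants
them.  Forked substrates mimic the quenched-flow constructs: a 33-bp duplex of
controlled GC count flanked by two 21-nt single-stranded arms.

Coordinates are 1-based from the hairpin base: the first base pair unwound is
position 1, matching an "unwound DNA (bp)" axis.  Mismatches (base changes on
the displaced strand) are stored as annotations consumed by the energetics
layer, not as a second strand, since only the displaced strand differs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "HairpinSubstrate",
    "ForkSubstrate",
    "make_hairpin",
    "make_mismatch_variant",
    "make_fork",
    "windowed_gc",
    "DEFAULT_HAIRPIN_CLUSTERS",
]

_BASES = np.array(list("ACGT"))

#: Cluster layout of the default 174-bp emulation hairpin: GC-rich windows
#: centred at 55, 90 and 120 bp.  This is a stand-in with the same designed
#: stability landscape as the experimental construct, not its sequence.
DEFAULT_HAIRPIN_CLUSTERS = ((55, 10, 0.9), (90, 10, 0.9), (120, 10, 0.9))


@dataclass(frozen=True)
class HairpinSubstrate:
    """A hairpin stem substrate.

    Parameters
    ----------
    name : str
        Label used in FASTA headers and provenance records.
    stem_sequence : str
        5'->3' sequence of the strand tracked by the helicase; its length is
        the number of base pairs in the stem.
    mismatch_positions : tuple of int
        1-based stem positions whose displaced-strand base is mutated
        (G -> T in the experimental design), breaking the base pair.
    loop_length : int
        Length of the capping loop in nucleotides (4 dT in the constructs).
    """

    name: str
    stem_sequence: str
    mismatch_positions: tuple[int, ...] = field(default_factory=tuple)
    loop_length: int = 4

    def __post_init__(self) -> None:
        seq = self.stem_sequence.upper()
        object.__setattr__(self, "stem_sequence", seq)
        if len(seq) == 0:
            raise ValueError("stem_sequence must be non-empty")
        if set(seq) - set("ACGT"):
            raise ValueError(f"invalid bases in stem_sequence: {set(seq) - set('ACGT')}")
        mm = tuple(sorted(int(p) for p in self.mismatch_positions))
        object.__setattr__(self, "mismatch_positions", mm)
        for p in mm:
            if not 1 <= p <= len(seq):
                raise ValueError(f"mismatch position {p} outside [1, {len(seq)}]")

    @property
    def length(self) -> int:
        return len(self.stem_sequence)


@dataclass(frozen=True)
class ForkSubstrate:
    """A forked duplex substrate: 33-bp duplex with two ssDNA arms."""

    name: str
    duplex_sequence: str
    arm_length: int = 21

    def __post_init__(self) -> None:
        seq = self.duplex_sequence.upper()
        object.__setattr__(self, "duplex_sequence", seq)
        if len(seq) != 33:
            raise ValueError(f"duplex must be 33 bp, got {len(seq)}")
        if set(seq) - set("ACGT"):
            raise ValueError("invalid bases in duplex_sequence")

    @property
    def gc_count(self) -> int:
        return sum(b in "GC" for b in self.duplex_sequence)

    @property
    def gc_percent(self) -> int:
        """GC content in percent, rounded (26/33 -> 79)."""
        return round(100 * self.gc_count / len(self.duplex_sequence))


def windowed_gc(sequence: str, window: int) -> np.ndarray:
    """Running GC fraction over windows of ``window`` bp.

    Returns one value per window start (length ``L - window + 1``).
    """
    is_gc = np.frombuffer(sequence.encode(), dtype=np.uint8)
    is_gc = ((is_gc == ord("G")) | (is_gc == ord("C"))).astype(float)
    kernel = np.ones(window) / window
    return np.convolve(is_gc, kernel, mode="valid")


def _draw_base(rng: np.random.Generator, gc_fraction: float) -> str:
    if rng.random() < gc_fraction:
        return "G" if rng.random() < 0.5 else "C"
    return "A" if rng.random() < 0.5 else "T"


def make_hairpin(
    length: int = 174,
    gc_clusters: tuple[tuple[int, int, float], ...] = DEFAULT_HAIRPIN_CLUSTERS,
    background_gc: float = 0.35,
    seed: int = 0,
    name: str | None = None,
) -> HairpinSubstrate:
    """Generate a hairpin stem with planted GC-rich clusters.

    Parameters
    ----------
    length : int
        Stem length in base pairs.
    gc_clusters : sequence of (center, width, gc_fraction)
        GC-rich windows; ``center`` is 1-based, the window spans
        ``center - width//2 .. center + (width - width//2) - 1``.
        Clusters may not overlap and must fit inside the stem.
    background_gc : float
        GC fraction outside the clusters.
    seed : int
        Seed for the base-composition draw; identical arguments and seed give
        identical sequences.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 <= background_gc <= 1.0:
        raise ValueError("background_gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)

    gc_target = np.full(length, float(background_gc))
    occupied = np.zeros(length, dtype=bool)
    for center, width, frac in gc_clusters:
        if not 0.0 <= frac <= 1.0:
            raise ValueError("cluster gc_fraction must lie in [0, 1]")
        lo = center - width // 2  # 1-based inclusive
        hi = lo + width - 1
        if lo < 1 or hi > length:
            raise ValueError(f"cluster at {center} (width {width}) outside [1, {length}]")
        sl = slice(lo - 1, hi)
        if occupied[sl].any():
            raise ValueError(f"cluster at {center} overlaps a previous cluster")
        occupied[sl] = True
        gc_target[sl] = frac

    # Deterministic composition: per window, place round(frac*width) G/C bases
    # at seeded-random positions so the realised windowed GC tracks the target
    # within 1/width even for short windows.
    seq = np.empty(length, dtype="<U1")
    segments: list[tuple[int, int, float]] = []
    prev = 0
    boundaries = np.flatnonzero(np.diff(gc_target) != 0) + 1
    for b in list(boundaries) + [length]:
        segments.append((prev, b, gc_target[prev]))
        prev = b
    for lo, hi, frac in segments:
        n = hi - lo
        n_gc = int(round(frac * n))
        flags = np.zeros(n, dtype=bool)
        flags[rng.permutation(n)[:n_gc]] = True
        strong = rng.choice(["G", "C"], size=n)
        weak = rng.choice(["A", "T"], size=n)
        seq[lo:hi] = np.where(flags, strong, weak)

    if name is None:
        name = f"hairpin{length}"
    return HairpinSubstrate(name=name, stem_sequence="".join(seq))


def make_mismatch_variant(
    substrate: HairpinSubstrate, positions: list[int] | tuple[int, ...]
) -> HairpinSubstrate:
    """Annotate displaced-strand mismatches (G -> T opposite a stem C).

    A position is eligible when the displaced strand carries a G there, i.e.
    the stem (tracking) strand base is C.  Ineligible positions are replaced
    by the nearest eligible one, which is recorded in the returned substrate's
    mismatch list.  The stem sequence itself is unchanged: only the displaced
    strand differs, and downstream energetics treat the position as unpaired.
    """
    if not positions:
        return substrate
    L = substrate.length
    eligible = [i + 1 for i, b in enumerate(substrate.stem_sequence) if b == "C"]
    if not eligible:
        raise ValueError("substrate has no C on the stem strand; no eligible mismatch site")
    chosen = []
    for p in positions:
        if not 1 <= int(p) <= L:
            raise ValueError(f"mismatch position {p} outside [1, {L}]")
        nearest = min(eligible, key=lambda q: (abs(q - p), q))
        chosen.append(nearest)
    mm = tuple(sorted(set(chosen)))
    name = f"{substrate.name}_mm{'_'.join(str(p) for p in mm)}"
    return replace(substrate, name=name, mismatch_positions=mm)


def make_fork(gc_count: int, seed: int = 0, name: str | None = None) -> ForkSubstrate:
    """Generate a 33-bp forked duplex with exactly ``gc_count`` G/C pairs.

    ``gc_count`` of 12, 16 and 26 reproduce the gc36, gc48 and gc79 designs
    (36%, 48% and 79% GC).
    """
    n = 33
    if not 0 <= gc_count <= n:
        raise ValueError(f"gc_count must lie in [0, {n}]")
    rng = np.random.default_rng(seed)
    flags = np.zeros(n, dtype=bool)
    flags[rng.permutation(n)[:gc_count]] = True
    strong = rng.choice(["G", "C"], size=n)
    weak = rng.choice(["A", "T"], size=n)
    seq = "".join(np.where(flags, strong, weak))
    if name is None:
        name = f"gc{round(100 * gc_count / n)}"
    return ForkSubstrate(name=name, duplex_sequence=seq)
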