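"""Repeat-motif algebra: canonical motifs, tandem-tiling purity, in-repeat-read calls.

A tandem repeat can be described by any rotation of its repeat unit on either
strand (GAAA, AAAG, TTTC, ... all name the same repeat).  Everything downstream
keys loci on a single *canonical* representative: the lexicographically smallest
string among all rotations of the primitive unit and of its reverse complement.
An in-repeat read (IRR) is a read whose sequence is (near-)entirely tandem
copies of one such unit; reads are scored by *purity*, the best fraction of
bases explained by a perfect tiling of the unit across the read.
"""

from __future__ import annotations

import dataclasses
from collections import Counter

import numpy as np

__all__ = [
    "MIN_UNIT",
    "MAX_UNIT",
    "Motif",
    "TandemRepeatLocus",
    "reverse_complement",
    "canonical_motif",
    "repeat_purity",
    "detect_irr",
]

MIN_UNIT = 2
MAX_UNIT = 20

_ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# uint8 code <-> base maps used by the vectorized paths (A=0 C=1 G=2 T=3,
# chosen so that complement == 3 - code).
BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE_OF = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_OF[_b] = _i
    _CODE_OF[ord(chr(_b).lower())] = _i


def reverse_complement(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A=0,C=1,G=2,T=3; anything else 255)."""
    return _CODE_OF[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode("ascii")


def _primitive(unit: str) -> str:
    """Smallest unit whose whole-number repetition reproduces ``unit``."""
    n = len(unit)
    for period in range(1, n):
        if n % period == 0 and unit[: period] * (n // period) == unit:
            return unit[:period]
    return unit


def _rotations(s: str):
    return (s[i:] + s[:i] for i in range(len(s)))


@dataclasses.dataclass(frozen=True, order=True)
class Motif:
    """A canonical repeat unit.

    The constructor enforces canonical form; build motifs from free-form
    units with :func:`canonical_motif`.
    """

    sequence: str

    def __post_init__(self):
        seq = self.sequence
        if not (MIN_UNIT <= len(seq) <= MAX_UNIT):
            raise ValueError(f"motif length must be in [{MIN_UNIT}, {MAX_UNIT}]: {seq!r}")
        if not set(seq) <= _ALPHABET:
            raise ValueError(f"motif must be upper-case ACGT: {seq!r}")
        if _primitive(seq) != seq:
            raise ValueError(f"motif is not primitive: {seq!r}")
        canon = min(min(_rotations(seq)), min(_rotations(reverse_complement(seq))))
        if canon != seq:
            raise ValueError(f"motif is not canonical: {seq!r} (canonical form {canon!r})")

    def __str__(self) -> str:
        return self.sequence

    def __len__(self) -> int:
        return len(self.sequence)


def canonical_motif(unit: str) -> Motif:
    """Canonicalize a repeat unit.

    The unit is reduced to its primitive period (ATAT -> AT), then mapped to
    the lexicographic minimum over all rotations of itself and of its reverse
    complement, so that every description of the same repeat on either strand
    collapses to one key (GAAA -> AAAG, CAG -> AGC).

    Raises
    ------
    ValueError
        for non-ACGT characters or a primitive period outside [2, 20].
    """
    unit = unit.upper()
    if not unit or not set(unit) <= _ALPHABET:
        raise ValueError(f"repeat unit must be non-empty ACGT text: {unit!r}")
    prim = _primitive(unit)
    if len(prim) < MIN_UNIT:
        raise ValueError(f"primitive unit is a homopolymer: {unit!r}")
    if len(prim) > MAX_UNIT:
        raise ValueError(f"primitive unit longer than {MAX_UNIT} bp: {unit!r}")
    canon = min(min(_rotations(prim)), min(_rotations(reverse_complement(prim))))
    return Motif(canon)


@dataclasses.dataclass(frozen=True, order=True)
class TandemRepeatLocus:
    """A genomic repeat interval (0-based half-open) keyed by canonical motif."""

    chrom: str
    start: int
    end: int
    motif: Motif

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.motif}"

    def __len__(self) -> int:
        return self.end - self.start


def _phase_purity(codes: np.ndarray, motif_codes: np.ndarray) -> float:
    """Best tiling-phase match fraction of one strand."""
    n = codes.size
    k = motif_codes.size
    idx = np.arange(n)
    best = 0
    for phase in range(k):
        matches = int(np.count_nonzero(codes == motif_codes[(idx + phase) % k]))
        if matches > best:
            best = matches
    return best / n


def repeat_purity(read_seq: str, motif: Motif | str) -> float:
    """Fraction of read bases explained by a perfect tandem tiling of ``motif``.

    The maximum is taken over both strands of the read and all tiling phases
    of the unit.  Ambiguous bases (N) always count as mismatches.
    """
    if not read_seq:
        raise ValueError("empty read")
    unit = str(motif).upper()
    if len(read_seq) < len(unit):
        raise ValueError("read shorter than motif")
    codes = encode(read_seq)
    mcodes = encode(unit)
    fwd = _phase_purity(codes, mcodes)
    # reverse-complement strand: complement = 3 - code (ambiguous codes stay
    # non-matching: 3-255 wraps to 4, outside the 0..3 base codes).
    rc = (np.uint8(3) - codes[::-1])
    rev = _phase_purity(rc, mcodes)
    return max(fwd, rev)


def _autocorrelation_periods(codes: np.ndarray, min_purity: float, unit_range) -> list[int]:
    """Candidate unit lengths by shift-k self agreement.

    If a read has purity q >= min_purity for period k then its shift-k
    agreement is at least 1 - 2(1-q)n/(n-k); periods failing that bound
    cannot carry a qualifying motif and are skipped.
    """
    n = codes.size
    lo, hi = unit_range
    periods = []
    for k in range(lo, min(hi, n // 2) + 1):
        bound = 1.0 - 2.0 * (1.0 - min_purity) * n / (n - k)
        agree = np.count_nonzero(codes[k:] == codes[:-k]) / (n - k)
        if agree >= bound - 1e-12:
            periods.append(k)
    return periods


def detect_irr(
    read_seq: str,
    min_purity: float = 0.9,
    unit_range: tuple[int, int] = (MIN_UNIT, MAX_UNIT),
) -> tuple[bool, Motif | None]:
    """Decide whether a read is an in-repeat read and name its motif.

    Candidate units are proposed from the read's own k-mers (k over
    ``unit_range``, restricted to periods passing a self-agreement screen),
    canonicalized, and scored with :func:`repeat_purity`; the best-scoring
    motif is returned when its purity reaches ``min_purity``.  Degenerate
    reads return ``(False, None)`` rather than raising.
    """
    read_seq = read_seq.upper()
    n = len(read_seq)
    if n < 2 * unit_range[0]:
        return False, None
    codes = encode(read_seq)
    best: tuple[float, str] | None = None  # (purity, sequence) at the winning unit length
    seen: set[str] = set()
    for k in _autocorrelation_periods(codes, min_purity, unit_range):
        counts = Counter(read_seq[i : i + k] for i in range(n - k + 1))
        for unit, count in counts.most_common(3):
            if count < 2:
                # a tandem unit recurs within its read; singletons are
                # flank-crossing chimeras, not repeat units
                continue
            try:
                motif = canonical_motif(unit)
            except ValueError:
                continue
            if len(motif) != k or motif.sequence in seen:
                continue
            seen.add(motif.sequence)
            purity = repeat_purity(read_seq, motif)
            if purity < min_purity:
                continue
            if best is None or purity > best[0] or (
                purity == best[0] and motif.sequence < best[1]
            ):
                best = (purity, motif.sequence)
        if best is not None:
            # parsimony: any read periodic at k is also periodic at multiples
            # of k, so a longer unit can only absorb errors; the shortest
            # qualifying unit is the repeat's true motif
            break
    if best is not None:
        return True, Motif(best[1])
    return False, None


def periodic_read_mask(
    seqs: np.ndarray,
    min_purity: float = 0.9,
    unit_range: tuple[int, int] = (MIN_UNIT, MAX_UNIT),
) -> np.ndarray:
    """Vectorized screen over a (reads x length) code matrix.

    Returns a boolean mask that is a superset of the reads passing
    :func:`detect_irr`; intended as the cheap first pass when classifying
    whole simulated read sets.
    """
    m, n = seqs.shape
    mask = np.zeros(m, dtype=bool)
    lo, hi = unit_range
    for k in range(lo, min(hi, n // 2) + 1):
        bound = 1.0 - 2.0 * (1.0 - min_purity) * n / (n - k)
        agree = np.count_nonzero(seqs[:, k:] == seqs[:, :-k], axis=1) / (n - k)
        mask |= agree >= bound - 1e-12
    return mask
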