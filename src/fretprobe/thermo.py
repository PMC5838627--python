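"""Nearest-neighbor duplex thermodynamics and two-state melting temperatures.

Duplex stability is modeled as a sum over adjacent base-pair stacks plus
per-terminus initiation terms (the unified Watson-Crick parameter set, with
published single-internal-mismatch stacks).  The melting temperature follows
the two-state convention

    Tm = dH * 1000 / (dS + R * ln(C_T / f)) - 273.15

with ``R = 1.987`` cal/(mol K), total strand concentration ``C_T`` and
``f = 4`` for non-self-complementary (``1`` for self-complementary) duplexes.
The 1 M Na+ reference Tm is adjusted to assay ionic conditions with the
Owczarzy reciprocal-temperature monovalent correction; Mg2+ enters through a
sodium-equivalent transform.  Temperatures are degrees Celsius at the API
surface and Kelvin internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from .errors import (
    AlphabetError,
    DomainError,
    NoTransitionError,
    ParameterCoverageError,
    RangeError,
    UnsupportedDuplexError,
)

R_GAS = 1.987  # cal / (mol K)
T37_K = 310.15
CELSIUS_OFFSET = 273.15

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
_VALID_BASES = frozenset("ACGT")


def _check_alphabet(seq: str, what: str = "sequence") -> str:
    seq = seq.upper()
    for i, base in enumerate(seq, start=1):
        if base not in _VALID_BASES:
            raise AlphabetError(f"{what} contains non-ACGT character {base!r} at position {i}")
    return seq


def complement(base: str) -> str:
    try:
        return _COMPLEMENT[base]
    except KeyError:
        raise AlphabetError(f"cannot complement non-ACGT base {base!r}") from None


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


def gc_fraction(seq: str) -> float:
    seq = seq.upper()
    return sum(b in "GC" for b in seq) / len(seq)


@dataclass(frozen=True)
class Oligo:
    """A 5'->3' DNA oligonucleotide with optional dye/tag labels.

    ``anchor`` is the 1-based reference-strand coordinate of the base the
    oligo's 5' end sits over; ``strand`` records whether the oligo's sequence
    matches the reference strand ("plus", i.e. it hybridizes to the
    complementary strand) or is its reverse complement ("minus").
    """

    name: str
    bases: str
    label5: str | None = None
    label3: str | None = None
    anchor: int | None = None
    strand: str = "plus"

    def __post_init__(self):
        if not self.bases:
            raise AlphabetError(f"oligo {self.name!r} has an empty sequence")
        object.__setattr__(self, "bases", _check_alphabet(self.bases, f"oligo {self.name!r}"))
        if self.anchor is not None and self.anchor < 1:
            raise RangeError(f"oligo {self.name!r}: anchor must be >= 1, got {self.anchor}")
        if self.strand not in ("plus", "minus"):
            raise ValueError(f"oligo {self.name!r}: strand must be 'plus' or 'minus'")

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def gc_fraction(self) -> float:
        return gc_fraction(self.bases)


@dataclass(frozen=True)
class BufferConditions:
    """Assay ionic conditions and total oligonucleotide concentration C_T.

    Defaults are a standard PCR buffer: 50 mM monovalent (Na+-equivalent)
    cations, 2 mM Mg2+ and 20 uM total strands.
    """

    monovalent_mM: float = 50.0
    divalent_mM: float = 2.0
    oligo_uM: float = 20.0
    self_complementary: bool = False

    def __post_init__(self):
        if self.monovalent_mM < 0 or self.divalent_mM < 0:
            raise DomainError("cation concentrations must be non-negative")
        if self.oligo_uM <= 0:
            raise DomainError("total oligo concentration must be positive")

    @property
    def sodium_equivalent_M(self) -> float:
        """Monovalent-equivalent cation concentration in mol/L.

        Divalent cations are folded in via Na_eq = mono + 120 * sqrt(Mg_mM)
        (concentrations in mM; von Ahsen-style transform).
        """
        return (self.monovalent_mM + 120.0 * math.sqrt(self.divalent_mM)) / 1000.0

    @property
    def ct_molar(self) -> float:
        return self.oligo_uM * 1e-6

    @property
    def symmetry_factor(self) -> float:
        return 1.0 if self.self_complementary else 4.0


@dataclass(frozen=True)
class DuplexSpec:
    """Base-by-base pairing of a probe against a target segment.

    ``target_segment`` is the stretch of the strand the probe hybridizes to,
    written 5'->3'; the probe pairs antiparallel, so probe base ``i``
    (1-based) pairs ``target_segment[L - i]`` (0-based).  ``pairs`` is ordered
    along the probe as (probe_base, target_base, is_watson_crick).
    """

    probe: Oligo
    target_segment: str
    pairs: tuple[tuple[str, str, bool], ...]
    mismatch_positions: tuple[int, ...]

    def __post_init__(self):
        if len(self.pairs) != len(self.probe.bases):
            raise ValueError("pairs must cover every probe base")
        expected = tuple(i for i, (_, _, wc) in enumerate(self.pairs, start=1) if not wc)
        if expected != tuple(self.mismatch_positions):
            raise ValueError("mismatch_positions inconsistent with pairs")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatch_positions)

    @property
    def gc_fraction(self) -> float:
        """GC fraction of the probe strand (used for the salt correction)."""
        return self.probe.gc_fraction


@dataclass(frozen=True)
class ThermoResult:
    """Duplex formation thermodynamics and two-state melting temperatures.

    dH in kcal/mol, dS in cal/(mol K), dG37 in kcal/mol; ``tm_1M`` is the
    melting temperature at the 1 M Na+ reference, ``tm_corrected`` under the
    supplied buffer.
    """

    dH: float
    dS: float
    dG37: float
    tm_1M: float
    tm_corrected: float


class NNParamTable:
    """Nearest-neighbor stack parameters loaded from plain-text TSV files.

    Entries map a stack key ``"XY/ZW"`` (top strand 5'-XY-3' over bottom
    strand 3'-ZW-5') to (dH kcal/mol, dS cal/(mol K)).  Lookup falls back to
    the reverse-complement-equivalent key ``"WZ/YX"`` so each physical stack
    is stored once.
    """

    def __init__(
        self,
        entries: dict[str, tuple[float, float]],
        init_at: tuple[float, float],
        init_gc: tuple[float, float],
        provenance: str,
    ):
        self.entries = dict(entries)
        self.init_at = init_at
        self.init_gc = init_gc
        self.provenance = provenance

    @classmethod
    def from_text(cls, *texts: str, provenance: str) -> "NNParamTable":
        entries: dict[str, tuple[float, float]] = {}
        init_at = init_gc = None
        for text in texts:
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("stack\t"):
                    continue
                key, dh, ds = line.split("\t")
                if key == "init_AT":
                    init_at = (float(dh), float(ds))
                elif key == "init_GC":
                    init_gc = (float(dh), float(ds))
                else:
                    entries[key] = (float(dh), float(ds))
        if init_at is None or init_gc is None:
            raise ValueError("parameter files missing initiation terms")
        return cls(entries, init_at, init_gc, provenance)

    @classmethod
    def from_files(cls, wc_path, mm_path, provenance: str) -> "NNParamTable":
        with open(wc_path) as f1, open(mm_path) as f2:
            return cls.from_text(f1.read(), f2.read(), provenance=provenance)

    @classmethod
    def default(cls) -> "NNParamTable":
        return _default_table()

    def stack(self, top: str, bottom: str) -> tuple[float, float]:
        """Parameters for stack 5'-top-3' / 3'-bottom-5' (both dinucleotides)."""
        key = f"{top}/{bottom}"
        hit = self.entries.get(key)
        if hit is None:
            # same physical stack read from the other strand
            alt = f"{bottom[::-1]}/{top[::-1]}"
            hit = self.entries.get(alt)
        if hit is None:
            raise ParameterCoverageError(key)
        return hit

    def initiation(self, terminal_probe_base: str) -> tuple[float, float]:
        return self.init_at if terminal_probe_base in "AT" else self.init_gc


@lru_cache(maxsize=1)
def _default_table() -> NNParamTable:
    data = resources.files("fretprobe.data")
    return NNParamTable.from_text(
        (data / "nn_watson_crick.tsv").read_text(),
        (data / "nn_internal_mismatch.tsv").read_text(),
        provenance=(
            "Unified Watson-Crick NN set (SantaLucia 1998) + internal single-mismatch "
            "sets (Allawi & SantaLucia 1997-1998; Peyret et al. 1999)"
        ),
    )


def align_probe(probe: Oligo, target: str, offset: int) -> DuplexSpec:
    """Align ``probe`` antiparallel against ``target`` (5'->3') at ``offset``.

    The probe footprint covers target positions ``offset .. offset+len-1``
    (1-based); probe base ``i`` pairs target base ``offset + len - i``, so the
    probe's 5' end sits over the 3'-most footprint base.  Pure function.
    """
    target = _check_alphabet(target, "target")
    n = len(probe.bases)
    if offset < 1 or offset + n - 1 > len(target):
        raise RangeError(
            f"probe of length {n} at offset {offset} does not fit in target of length {len(target)}"
        )
    segment = target[offset - 1 : offset - 1 + n]
    pairs = []
    mismatches = []
    for i, pb in enumerate(probe.bases, start=1):
        tb = segment[n - i]  # antiparallel partner
        wc = _COMPLEMENT[pb] == tb
        pairs.append((pb, tb, wc))
        if not wc:
            mismatches.append(i)
    return DuplexSpec(
        probe=probe,
        target_segment=segment,
        pairs=tuple(pairs),
        mismatch_positions=tuple(mismatches),
    )


def nn_sum(duplex: DuplexSpec, params: NNParamTable | None = None) -> tuple[float, float]:
    """Sum nearest-neighbor stacks and initiation terms for a duplex.

    Supports perfect duplexes and duplexes with exactly one internal
    mismatch; terminal mismatches and multiple mismatches are rejected.
    Returns (dH kcal/mol, dS cal/(mol K)).
    """
    params = params or NNParamTable.default()
    n = len(duplex)
    if n < 2:
        raise UnsupportedDuplexError("duplex must have at least 2 base pairs")
    if duplex.n_mismatches > 1:
        raise UnsupportedDuplexError(
            f"{duplex.n_mismatches} mismatches at {duplex.mismatch_positions}; at most 1 supported"
        )
    if any(p in (1, n) for p in duplex.mismatch_positions):
        raise UnsupportedDuplexError("terminal mismatches are not supported")

    probe_seq = duplex.probe.bases
    partners = "".join(tb for _, tb, _ in duplex.pairs)  # bottom strand, 3'->5', probe order
    terms = [params.stack(probe_seq[i : i + 2], partners[i : i + 2]) for i in range(n - 1)]
    terms += [params.initiation(probe_seq[end]) for end in (0, -1)]
    # fsum: correctly rounded, so the result is independent of stack order
    # (exact strand symmetry under probe/target role swap)
    return math.fsum(t[0] for t in terms), math.fsum(t[1] for t in terms)


def salt_adjust(
    tm_1M: float, duplex_gc_fraction: float, length_bp: int, buffer: BufferConditions
) -> float:
    """Correct a 1 M Na+ reference Tm (degC) to the buffer's ionic conditions.

    Owczarzy et al. (2004) reciprocal correction:

        1/Tm[Na] = 1/Tm[1M] + (4.29 fGC - 3.95)e-5 ln[Na] + 9.40e-6 ln^2[Na]

    with [Na] the sodium-equivalent molar concentration (Mg2+ folded in via
    ``BufferConditions.sodium_equivalent_M``).  ``length_bp`` is validated but
    does not enter this particular published formula.
    """
    if not 0.0 <= duplex_gc_fraction <= 1.0:
        raise DomainError(f"gc fraction must be in [0, 1], got {duplex_gc_fraction}")
    if length_bp < 2:
        raise DomainError(f"duplex length must be >= 2 bp, got {length_bp}")
    na = buffer.sodium_equivalent_M
    if na <= 0:
        raise DomainError("sodium-equivalent concentration must be positive for salt correction")
    ln_na = math.log(na)
    inv = 1.0 / (tm_1M + CELSIUS_OFFSET)
    inv += (4.29 * duplex_gc_fraction - 3.95) * 1e-5 * ln_na
    inv += 9.40e-6 * ln_na * ln_na
    return 1.0 / inv - CELSIUS_OFFSET


def two_state_tm(
    dH: float,
    dS: float,
    buffer: BufferConditions,
    gc_fraction: float = 0.5,
    length_bp: int = 16,
    steric_tm_offset_c: float = 0.0,
) -> ThermoResult:
    """Two-state melting temperature from duplex formation dH/dS.

    ``gc_fraction`` and ``length_bp`` only enter the salt correction of
    ``tm_corrected``; ``tm_1M`` depends on dH, dS and C_T alone.
    ``steric_tm_offset_c`` is an optional constant offset modelling dye
    steric effects (default 0).
    """
    denom = dS + R_GAS * math.log(buffer.ct_molar / buffer.symmetry_factor)
    if denom >= 0:
        raise NoTransitionError(
            f"no two-state transition: dS + R ln(C_T/f) = {denom:.3f} >= 0"
        )
    tm_1m = dH * 1000.0 / denom - CELSIUS_OFFSET
    tm_corr = salt_adjust(tm_1m, gc_fraction, length_bp, buffer) + steric_tm_offset_c
    dg37 = dH - T37_K * dS / 1000.0
    return ThermoResult(dH=dH, dS=dS, dG37=dg37, tm_1M=tm_1m, tm_corrected=tm_corr)


def duplex_thermo(
    duplex: DuplexSpec,
    buffer: BufferConditions,
    params: NNParamTable | None = None,
    steric_tm_offset_c: float = 0.0,
) -> ThermoResult:
    """Convenience: nn_sum + two_state_tm with the duplex's own GC and length."""
    dh, ds = nn_sum(duplex, params)
    return two_state_tm(
        dh,
        ds,
        buffer,
        gc_fraction=duplex.gc_fraction,
        length_bp=len(duplex),
        steric_tm_offset_c=steric_tm_offset_c,
    )


def delta_tm(
    probe: Oligo,
    target_ref: str,
    target_alt: str,
    offset: int,
    buffer: BufferConditions,
    params: NNParamTable | None = None,
) -> tuple[float, float, float]:
    """Per-allele probe Tms and their difference.

    Returns ``(tm_ref, tm_alt, delta)`` in degC under the buffer, with
    ``delta = tm_ref - tm_alt``; when the probe perfectly matches the
    reference target, delta is the allele-discrimination signal and is
    non-negative.
    """
    t_ref = duplex_thermo(align_probe(probe, target_ref, offset), buffer, params)
    t_alt = duplex_thermo(align_probe(probe, target_alt, offset), buffer, params)
    return t_ref.tm_corrected, t_alt.tm_corrected, t_ref.tm_corrected - t_alt.tm_corrected
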