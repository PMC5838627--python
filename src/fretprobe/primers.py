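"""Nested (two-round) PCR primer design and validation around a probe footprint.

The outer primer pair defines a first-round amplicon; the inner pair sits
strictly inside it and defines the second-round amplicon, which must still
contain the full donor+acceptor probe footprint.  Primers are plain
(unlabeled) oligos; quality is scored as the weighted deviation from the
middle of the Tm and GC windows plus penalties for stable self-dimers and
hairpins, so a best-scoring set always exists whenever the geometry fits.

Coordinate convention: a primer's ``anchor`` is the reference-strand
coordinate of its 5' base — the leftmost footprint base for forward primers
and the rightmost for reverse primers.  Amplicon boundaries are the forward
anchor and the reverse anchor, inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

from .design import SNPLocus, hairpin_screen
from .errors import ValidationError
from .thermo import (
    BufferConditions,
    NNParamTable,
    Oligo,
    T37_K,
    align_probe,
    duplex_thermo,
    gc_fraction,
    reverse_complement,
)


@dataclass(frozen=True)
class PrimerConstraints:
    """Search windows and scoring weights for primer design."""

    length_range: tuple[int, int] = (18, 24)
    tm_window: tuple[float, float] = (55.0, 65.0)
    gc_window: tuple[float, float] = (0.40, 0.60)
    min_flank: int = 3  # nt between a primer 3' end and the region it must flank
    search_span: int = 40  # how far outward candidate 3' ends are explored
    weight_tm: float = 1.0  # score units per degC deviation from the Tm midpoint
    weight_gc: float = 25.0  # per unit GC-fraction deviation from the midpoint
    weight_structure: float = 2.0  # per kcal/mol of dimer/hairpin excess stability
    dimer_dg37_floor: float = -6.0  # self-dimers more stable than this are penalized
    hairpin_dg37_floor: float = -3.0


@dataclass(frozen=True)
class PrimerReport:
    tm_c: float
    gc: float
    self_dimer_dg37: float | None
    hairpin_dg37: float | None
    three_prime_dg37: float


@dataclass(frozen=True)
class PrimerSet:
    outer_forward: Oligo
    outer_reverse: Oligo
    inner_forward: Oligo
    inner_reverse: Oligo
    outer_amplicon: tuple[int, int]
    inner_amplicon: tuple[int, int]
    probe_footprint: tuple[int, int] | None = None
    reports: dict | None = None

    def oligos(self) -> tuple[Oligo, Oligo, Oligo, Oligo]:
        return (self.outer_forward, self.outer_reverse, self.inner_forward, self.inner_reverse)

    @property
    def outer_length(self) -> int:
        return self.outer_amplicon[1] - self.outer_amplicon[0] + 1

    @property
    def inner_length(self) -> int:
        return self.inner_amplicon[1] - self.inner_amplicon[0] + 1


@dataclass(frozen=True)
class PrimerDesignOutcome:
    primer_set: PrimerSet | None
    diagnostics: tuple[str, ...] = ()

    def __bool__(self) -> bool:
        return self.primer_set is not None


def _self_dimer_dg37(seq: str, params: NNParamTable) -> float | None:
    """Most stable antiparallel self-alignment, scored by WC stacks only.

    Slides the oligo against a second copy of itself in every antiparallel
    register, finds contiguous complementary runs of >= 2 pairs and scores
    their stacks; returns the most negative total dG37 (None if no run).
    """
    n = len(seq)
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    best: float | None = None
    for c in range(2 * n - 2):  # position i of copy 1 pairs position c - i of copy 2
        run: list[int] = []
        for i in range(n):
            j = c - i
            paired = 0 <= j < n and comp[seq[i]] == seq[j]
            if paired:
                run.append(i)
            if not paired or i == n - 1:
                if len(run) >= 2:
                    dg = 0.0
                    for k in range(len(run) - 1):
                        a = run[k]
                        top = seq[a : a + 2]
                        dh, ds = params.stack(top, comp[top[0]] + comp[top[1]])
                        dg += dh - T37_K * ds / 1000.0
                    if best is None or dg < best:
                        best = dg
                run = []
    return best


def evaluate_primer(
    oligo: Oligo, buffer: BufferConditions, params: NNParamTable | None = None
) -> PrimerReport:
    """Standard primer quality metrics for a single oligo.

    Tm is the perfect-duplex two-state Tm under the buffer; 3' stability is
    the summed dG37 of the five 3'-terminal stacks (more negative = a
    stickier, more extension-prone 3' end).
    """
    if len(oligo) < 10:
        raise ValidationError(f"primer {oligo.name!r} shorter than 10 nt")
    params = params or NNParamTable.default()
    thermo = duplex_thermo(align_probe(oligo, reverse_complement(oligo.bases), 1), buffer, params)
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    three_prime = 0.0
    for a in range(len(oligo) - 6, len(oligo) - 1):
        top = oligo.bases[a : a + 2]
        dh, ds = params.stack(top, comp[top[0]] + comp[top[1]])
        three_prime += dh - T37_K * ds / 1000.0
    hp = hairpin_screen(oligo.bases, params)
    return PrimerReport(
        tm_c=thermo.tm_corrected,
        gc=gc_fraction(oligo.bases),
        self_dimer_dg37=_self_dimer_dg37(oligo.bases, params),
        hairpin_dg37=hp.worst_dg37,
        three_prime_dg37=three_prime,
    )


def _score(report: PrimerReport, constraints: PrimerConstraints) -> float:
    tm_mid = 0.5 * (constraints.tm_window[0] + constraints.tm_window[1])
    gc_mid = 0.5 * (constraints.gc_window[0] + constraints.gc_window[1])
    score = constraints.weight_tm * abs(report.tm_c - tm_mid)
    score += constraints.weight_gc * abs(report.gc - gc_mid)
    if report.self_dimer_dg37 is not None:
        score += constraints.weight_structure * max(
            0.0, constraints.dimer_dg37_floor - report.self_dimer_dg37
        )
    if report.hairpin_dg37 is not None:
        score += constraints.weight_structure * max(
            0.0, constraints.hairpin_dg37_floor - report.hairpin_dg37
        )
    return score


def _primer_at(locus_seq: str, three_prime_pos: int, length: int, forward: bool, name: str) -> Oligo:
    if forward:
        start = three_prime_pos - length + 1
        return Oligo(name=name, bases=locus_seq[start - 1 : three_prime_pos], anchor=start,
                     strand="plus")
    end = three_prime_pos + length - 1
    return Oligo(
        name=name,
        bases=reverse_complement(locus_seq[three_prime_pos - 1 : end]),
        anchor=end,
        strand="minus",
    )


def _best_slot(
    locus_seq: str,
    forward: bool,
    inner_limit: int,
    outer_limit: int,
    name: str,
    constraints: PrimerConstraints,
    buffer: BufferConditions,
    params: NNParamTable,
) -> tuple[Oligo, PrimerReport] | None:
    """Best primer whose 3' end lies between inner_limit and outer_limit.

    For forward primers the 3' end runs leftward from ``inner_limit``; for
    reverse primers rightward.  Candidates are enumerated in a fixed order
    (3' end from the region outward, then increasing length) so ties resolve
    deterministically to the innermost, shortest primer.
    """
    best = None
    step = -1 if forward else 1
    for three_prime in range(inner_limit, outer_limit + step, step):
        for length in range(constraints.length_range[0], constraints.length_range[1] + 1):
            if forward:
                start = three_prime - length + 1
                if start < 1:
                    continue
            else:
                if three_prime + length - 1 > len(locus_seq):
                    continue
            oligo = _primer_at(locus_seq, three_prime, length, forward, name)
            report = evaluate_primer(oligo, buffer, params)
            score = _score(report, constraints)
            if best is None or score < best[0]:
                best = (score, oligo, report)
    if best is None:
        return None
    return best[1], best[2]


def design_nested_primers(
    locus: SNPLocus,
    probe_footprint: tuple[int, int],
    constraints: PrimerConstraints | None = None,
    buffer: BufferConditions | None = None,
    params: NNParamTable | None = None,
) -> PrimerDesignOutcome:
    """Design outer+inner primer pairs flanking the probe footprint.

    Inner primers flank the footprint by at least ``min_flank`` nt; outer
    primers sit strictly outside the inner primer footprints.  Each of the
    four slots takes its best-scoring candidate; the search is deterministic
    given the configuration.  Returns an outcome with the violated geometric
    constraint in ``diagnostics`` when no candidate fits.
    """
    constraints = constraints or PrimerConstraints()
    buffer = buffer or BufferConditions()
    params = params or NNParamTable.default()
    seq = locus.sequence
    fp_start, fp_end = probe_footprint
    if not (1 <= fp_start <= fp_end <= len(seq)):
        return PrimerDesignOutcome(None, (f"probe footprint {probe_footprint} outside locus",))

    diags = []
    inner_fw_limit = fp_start - 1 - constraints.min_flank
    inner_rv_limit = fp_end + 1 + constraints.min_flank
    inner_fw = _best_slot(
        seq, True, inner_fw_limit, max(1, inner_fw_limit - constraints.search_span),
        "inner_forward", constraints, buffer, params,
    )
    inner_rv = _best_slot(
        seq, False, inner_rv_limit, min(len(seq), inner_rv_limit + constraints.search_span),
        "inner_reverse", constraints, buffer, params,
    )
    if inner_fw is None:
        diags.append("no room for an inner forward primer left of the probe footprint")
    if inner_rv is None:
        diags.append("no room for an inner reverse primer right of the probe footprint")
    if diags:
        return PrimerDesignOutcome(None, tuple(diags))

    ifw_start = inner_fw[0].anchor
    irv_end = inner_rv[0].anchor
    outer_fw = _best_slot(
        seq, True, ifw_start - 1, max(1, ifw_start - 1 - constraints.search_span),
        "outer_forward", constraints, buffer, params,
    )
    outer_rv = _best_slot(
        seq, False, irv_end + 1, min(len(seq), irv_end + 1 + constraints.search_span),
        "outer_reverse", constraints, buffer, params,
    )
    if outer_fw is None:
        diags.append("no room for an outer forward primer outside the inner amplicon")
    if outer_rv is None:
        diags.append("no room for an outer reverse primer outside the inner amplicon")
    if diags:
        return PrimerDesignOutcome(None, tuple(diags))

    pset = PrimerSet(
        outer_forward=outer_fw[0],
        outer_reverse=outer_rv[0],
        inner_forward=inner_fw[0],
        inner_reverse=inner_rv[0],
        outer_amplicon=(outer_fw[0].anchor, outer_rv[0].anchor),
        inner_amplicon=(inner_fw[0].anchor, inner_rv[0].anchor),
        probe_footprint=probe_footprint,
        reports={
            "outer_forward": outer_fw[1],
            "outer_reverse": outer_rv[1],
            "inner_forward": inner_fw[1],
            "inner_reverse": inner_rv[1],
        },
    )
    return PrimerDesignOutcome(pset, ())


def primer_set_from_oligos(
    outer_forward: Oligo,
    outer_reverse: Oligo,
    inner_forward: Oligo,
    inner_reverse: Oligo,
    probe_footprint: tuple[int, int] | None = None,
) -> PrimerSet:
    """Assemble a PrimerSet from explicit anchored oligos (e.g. a published set)."""
    for o in (outer_forward, outer_reverse, inner_forward, inner_reverse):
        if o.anchor is None:
            raise ValidationError(f"primer {o.name!r} has no anchor coordinate")
    return PrimerSet(
        outer_forward=outer_forward,
        outer_reverse=outer_reverse,
        inner_forward=inner_forward,
        inner_reverse=inner_reverse,
        outer_amplicon=(outer_forward.anchor, outer_reverse.anchor),
        inner_amplicon=(inner_forward.anchor, inner_reverse.anchor),
        probe_footprint=probe_footprint,
    )


def validate_primer_set(pset: PrimerSet, locus: SNPLocus | str) -> list[str]:
    """Independent re-check of a primer set against the locus sequence.

    Verifies footprint identity on the correct strand, amplicon bookkeeping,
    strict nesting, probe-footprint coverage (when recorded) and uniqueness
    of each primer's exact binding site.  Returns violation messages
    (empty list = valid).
    """
    seq = locus.sequence if isinstance(locus, SNPLocus) else str(locus).upper()
    v: list[str] = []

    def footprint(o: Oligo) -> tuple[int, int]:
        if o.strand == "plus":
            return o.anchor, o.anchor + len(o) - 1
        return o.anchor - len(o) + 1, o.anchor

    for o, expect_fwd in (
        (pset.outer_forward, True),
        (pset.outer_reverse, False),
        (pset.inner_forward, True),
        (pset.inner_reverse, False),
    ):
        if (o.strand == "plus") != expect_fwd:
            v.append(f"{o.name}: expected {'plus' if expect_fwd else 'minus'} strand")
            continue
        start, end = footprint(o)
        if start < 1 or end > len(seq):
            v.append(f"{o.name}: footprint {start}..{end} outside locus")
            continue
        site = seq[start - 1 : end]
        expected = o.bases if o.strand == "plus" else reverse_complement(o.bases)
        if site != expected:
            v.append(f"{o.name}: sequence does not match locus at {start}..{end}")
        hits = 0
        for needle in {o.bases, reverse_complement(o.bases)}:
            i = 0
            while True:
                i = seq.find(needle, i)
                if i < 0:
                    break
                hits += 1
                i += 1
        if hits != 1:
            v.append(f"{o.name}: {hits} exact binding sites in locus (expected 1)")

    o_start, o_end = pset.outer_amplicon
    i_start, i_end = pset.inner_amplicon
    if (o_start, o_end) != (pset.outer_forward.anchor, pset.outer_reverse.anchor):
        v.append("outer amplicon does not match outer primer anchors")
    if (i_start, i_end) != (pset.inner_forward.anchor, pset.inner_reverse.anchor):
        v.append("inner amplicon does not match inner primer anchors")
    ofw_end = footprint(pset.outer_forward)[1]
    orv_start = footprint(pset.outer_reverse)[0]
    if not (ofw_end < footprint(pset.inner_forward)[0] and
            footprint(pset.inner_reverse)[1] < orv_start):
        v.append("inner primers are not strictly nested inside the outer primer footprints")
    if not (o_start <= i_start and i_end <= o_end and (i_start, i_end) != (o_start, o_end)):
        v.append("inner amplicon not strictly inside outer amplicon")
    if pset.probe_footprint is not None:
        fp_start, fp_end = pset.probe_footprint
        for label, (s, e) in (("outer", pset.outer_amplicon), ("inner", pset.inner_amplicon)):
            if not (s <= fp_start and fp_end <= e):
                v.append(f"probe footprint {pset.probe_footprint} not inside {label} amplicon")
        ifw_end = footprint(pset.inner_forward)[1]
        irv_start = footprint(pset.inner_reverse)[0]
        if not (ifw_end < fp_start and fp_end < irv_start):
            v.append("inner primers overlap the probe footprint")
    return v
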