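"""FRET probe-pair design: acceptor length scan, donor placement, hairpin screen.

The sensor (acceptor) probe spans the SNP; its per-allele melting
temperatures are computed with the nearest-neighbor engine and the scan
selects the length maximizing the allele-discrimination dTm subject to a
working Tm window.  The anchor (donor) probe is then placed adjacent to the
sensor with a 1-5 nt gap so the two dyes (donor 3' dye, acceptor 5' dye)
come into FRET proximity, with the donor melting above the sensor so the
sensor transition dominates the observed melting peak.  A simplified
stem-loop scan screens the probe-binding region for stable hairpins that
could compete with probe hybridization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .errors import CoverageError, PlacementError, ValidationError
from .thermo import (
    BufferConditions,
    NNParamTable,
    Oligo,
    T37_K,
    align_probe,
    duplex_thermo,
    reverse_complement,
)

DONOR_DYE = "fluorescein"
ACCEPTOR_DYE = "Red640"
PHOSPHATE_BLOCK = "phosphate"


@dataclass(frozen=True)
class SNPLocus:
    """A reference-strand sequence with a single biallelic SNP.

    ``sequence`` is the designated reference strand 5'->3'; the base at
    ``snp_position`` (1-based) must equal ``ref_allele``.  Note the allele
    letters are as they read on *this* strand; a SNP reported on the opposite
    strand appears complemented here.
    """

    sequence: str
    snp_position: int
    ref_allele: str
    alt_allele: str
    name: str = ""

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "ref_allele", self.ref_allele.upper())
        object.__setattr__(self, "alt_allele", self.alt_allele.upper())
        if not (1 <= self.snp_position <= len(seq)):
            raise ValidationError(
                f"snp_position {self.snp_position} outside sequence of length {len(seq)}"
            )
        if self.ref_allele not in "ACGT" or self.alt_allele not in "ACGT":
            raise ValidationError("alleles must be single bases in {A,C,G,T}")
        if self.ref_allele == self.alt_allele:
            raise ValidationError("ref and alt alleles must differ")
        if seq[self.snp_position - 1] != self.ref_allele:
            raise ValidationError(
                f"sequence has {seq[self.snp_position - 1]!r} at snp_position "
                f"{self.snp_position}, expected ref allele {self.ref_allele!r}"
            )

    def allele_sequence(self, allele: str) -> str:
        """Full reference-strand sequence carrying the given allele base."""
        allele = allele.upper()
        if allele not in (self.ref_allele, self.alt_allele):
            raise ValidationError(f"allele {allele!r} is neither ref nor alt")
        s = list(self.sequence)
        s[self.snp_position - 1] = allele
        return "".join(s)


@dataclass(frozen=True)
class DesignConstraints:
    """Tunable design windows.  Temperatures degC, lengths nt."""

    acceptor_length_range: tuple[int, int] = (12, 24)
    donor_length_range: tuple[int, int] = (16, 28)
    gap_range: tuple[int, int] = (1, 5)
    delta_tm_min: float = 5.0
    acceptor_tm_window: tuple[float, float] = (45.0, 70.0)
    donor_minus_acceptor_tm_min: float = 2.0

    def __post_init__(self):
        for lo, hi, what in (
            (*self.acceptor_length_range, "acceptor_length_range"),
            (*self.donor_length_range, "donor_length_range"),
            (*self.gap_range, "gap_range"),
            (*self.acceptor_tm_window, "acceptor_tm_window"),
        ):
            if lo > hi:
                raise ValidationError(f"{what} is empty: {(lo, hi)}")
        if not (1 <= self.gap_range[0] and self.gap_range[1] <= 5):
            raise ValidationError(f"gap_range must lie within [1, 5], got {self.gap_range}")
        if self.delta_tm_min <= 0:
            raise ValidationError("delta_tm_min must be positive")


@dataclass(frozen=True)
class ScanAnchor:
    """Anchoring of the acceptor length scan.

    ``fixed_end`` names which footprint edge (in reference-strand
    coordinates) stays put while the probe extends away from it; ``position``
    is that edge's 1-based coordinate.  ``probe_matches`` selects the probe
    orientation: "plus" probes read the reference strand (and hybridize to
    its complement), "minus" probes are the reverse complement (and hybridize
    to the reference strand itself).
    """

    position: int
    fixed_end: str = "left"
    probe_matches: str = "plus"

    def __post_init__(self):
        if self.fixed_end not in ("left", "right"):
            raise ValidationError("fixed_end must be 'left' or 'right'")
        if self.probe_matches not in ("plus", "minus"):
            raise ValidationError("probe_matches must be 'plus' or 'minus'")

    def footprint(self, length: int) -> tuple[int, int]:
        if self.fixed_end == "left":
            return self.position, self.position + length - 1
        return self.position - length + 1, self.position


@dataclass(frozen=True)
class LengthScanRow:
    length: int
    tm_match: float
    tm_mismatch: float
    delta_tm: float
    probe: Oligo
    footprint: tuple[int, int]


@dataclass(frozen=True)
class LengthScanResult:
    rows: tuple[LengthScanRow, ...]
    anchor: ScanAnchor
    locus_name: str = ""

    def row_for_length(self, length: int) -> LengthScanRow:
        for r in self.rows:
            if r.length == length:
                return r
        raise KeyError(f"no scan row for length {length}")


@dataclass(frozen=True)
class HairpinResult:
    """Worst stem-loop candidate found in a region (None if no candidate)."""

    worst_dg37: float | None
    flagged: bool
    stem_bp: int = 0
    loop_nt: int = 0
    position: int = 0


@dataclass(frozen=True)
class ProbePairDesign:
    donor: Oligo
    acceptor: Oligo
    gap_nt: int
    tm_ref: float
    tm_alt: float
    delta_tm: float
    hairpin_flagged: bool
    hairpin_dg37: float | None
    rationale: str
    acceptor_footprint: tuple[int, int]
    donor_footprint: tuple[int, int]
    probe_matches: str


@dataclass(frozen=True)
class DesignOutcome:
    """Result wrapper: the chosen design, or None plus per-stage diagnostics."""

    design: ProbePairDesign | None
    diagnostics: tuple[str, ...] = ()

    def __bool__(self) -> bool:
        return self.design is not None


def _probe_and_targets(
    locus: SNPLocus, footprint: tuple[int, int], probe_matches: str
) -> tuple[Oligo, str, str]:
    """Build the scan probe (from the ref allele) and its per-allele targets.

    Returns (probe, matched_target_segment, mismatched_target_segment), both
    targets 5'->3' on the strand the probe hybridizes to.
    """
    start, end = footprint
    ref_fp = locus.allele_sequence(locus.ref_allele)[start - 1 : end]
    alt_fp = locus.allele_sequence(locus.alt_allele)[start - 1 : end]
    if probe_matches == "plus":
        probe_seq = ref_fp
        target_ref, target_alt = reverse_complement(ref_fp), reverse_complement(alt_fp)
    else:
        probe_seq = reverse_complement(ref_fp)
        target_ref, target_alt = ref_fp, alt_fp
    probe = Oligo(
        name=f"scan_{start}_{end}_{probe_matches}",
        bases=probe_seq,
        anchor=end if probe_matches == "minus" else start,
        strand=probe_matches,
    )
    return probe, target_ref, target_alt


def length_scan(
    locus: SNPLocus,
    anchor: ScanAnchor,
    lengths,
    buffer: BufferConditions,
    params: NNParamTable | None = None,
) -> LengthScanResult:
    """Per-length matched/mismatched Tm of SNP-covering acceptor candidates.

    Every scanned footprint must cover the SNP strictly in its interior
    (terminal-mismatch duplexes are outside the supported parameter regime);
    otherwise a CoverageError is raised.
    """
    lengths = list(lengths)
    if not lengths:
        raise ValidationError("empty length range for scan")
    rows = []
    for length in lengths:
        start, end = anchor.footprint(length)
        if start < 1 or end > len(locus.sequence):
            raise CoverageError(
                f"footprint {start}..{end} (length {length}) outside locus of "
                f"length {len(locus.sequence)}"
            )
        if not (start < locus.snp_position < end):
            raise CoverageError(
                f"footprint {start}..{end} does not strictly cover SNP at "
                f"{locus.snp_position}"
            )
        probe, t_ref, t_alt = _probe_and_targets(locus, (start, end), anchor.probe_matches)
        res_ref = duplex_thermo(align_probe(probe, t_ref, 1), buffer, params)
        res_alt = duplex_thermo(align_probe(probe, t_alt, 1), buffer, params)
        rows.append(
            LengthScanRow(
                length=length,
                tm_match=res_ref.tm_corrected,
                tm_mismatch=res_alt.tm_corrected,
                delta_tm=res_ref.tm_corrected - res_alt.tm_corrected,
                probe=probe,
                footprint=(start, end),
            )
        )
    return LengthScanResult(rows=tuple(rows), anchor=anchor, locus_name=locus.name)


def select_acceptor(
    scan: LengthScanResult, constraints: DesignConstraints
) -> LengthScanRow | None:
    """Best qualifying scan row: maximal dTm, ties to shorter length, lower Tm.

    Qualifying rows have dTm >= delta_tm_min and tm_match inside the working
    acceptor Tm window.  Returns None (an explicit no-candidate outcome) when
    nothing qualifies.
    """
    if not scan.rows:
        raise ValidationError("cannot select from an empty scan")
    lo, hi = constraints.acceptor_tm_window
    qualifying = [
        r
        for r in scan.rows
        if r.delta_tm >= constraints.delta_tm_min and lo <= r.tm_match <= hi
    ]
    if not qualifying:
        return None
    return min(qualifying, key=lambda r: (-r.delta_tm, r.length, r.tm_match))


def place_donor(
    locus: SNPLocus,
    acceptor: Oligo,
    constraints: DesignConstraints,
    buffer: BufferConditions,
    params: NNParamTable | None = None,
) -> Oligo:
    """Place the donor (anchor) probe adjacent to the chosen acceptor.

    FRET geometry fixes the donor side: the donor's 3' dye must face the
    acceptor's 5' dye across the gap.  For a plus-matching acceptor the
    donor sits on the lower-coordinate side; for a minus-matching acceptor on
    the higher-coordinate side.  The smallest gap, then the shortest donor
    whose Tm exceeds the acceptor's matched Tm by the configured margin, is
    chosen.  The SNP must not fall under the donor footprint.
    """
    if acceptor.anchor is None:
        raise PlacementError("acceptor must carry a genomic anchor")
    if acceptor.strand == "plus":
        acc_start, acc_end = acceptor.anchor, acceptor.anchor + len(acceptor) - 1
    else:
        acc_start, acc_end = acceptor.anchor - len(acceptor) + 1, acceptor.anchor

    acc_thermo = duplex_thermo(
        align_probe(
            acceptor,
            reverse_complement(locus.allele_sequence(locus.ref_allele)[acc_start - 1 : acc_end])
            if acceptor.strand == "plus"
            else locus.allele_sequence(locus.ref_allele)[acc_start - 1 : acc_end],
            1,
        ),
        buffer,
        params,
    )
    tm_floor = acc_thermo.tm_corrected + constraints.donor_minus_acceptor_tm_min

    g_lo, g_hi = constraints.gap_range
    l_lo, l_hi = constraints.donor_length_range
    attempts = []
    for gap in range(g_lo, g_hi + 1):
        for length in range(l_lo, l_hi + 1):
            if acceptor.strand == "plus":
                d_end = acc_start - 1 - gap
                d_start = d_end - length + 1
            else:
                d_start = acc_end + 1 + gap
                d_end = d_start + length - 1
            if d_start < 1 or d_end > len(locus.sequence):
                attempts.append(f"gap {gap} length {length}: footprint outside locus")
                continue
            if d_start <= locus.snp_position <= d_end:
                attempts.append(f"gap {gap} length {length}: SNP under donor footprint")
                continue
            fp_seq = locus.sequence[d_start - 1 : d_end]
            if acceptor.strand == "plus":
                donor = Oligo(
                    name="donor",
                    bases=fp_seq,
                    label3=DONOR_DYE,
                    anchor=d_start,
                    strand="plus",
                )
                target = reverse_complement(fp_seq)
            else:
                donor = Oligo(
                    name="donor",
                    bases=reverse_complement(fp_seq),
                    label3=DONOR_DYE,
                    anchor=d_end,
                    strand="minus",
                )
                target = fp_seq
            thermo = duplex_thermo(align_probe(donor, target, 1), buffer, params)
            if thermo.tm_corrected >= tm_floor:
                return donor
            attempts.append(
                f"gap {gap} length {length}: donor Tm {thermo.tm_corrected:.2f} degC "
                f"below floor {tm_floor:.2f} degC"
            )
    raise PlacementError(
        "no donor placement satisfies the constraints; tried: " + "; ".join(attempts[-5:])
    )


def hairpin_screen(
    region: str,
    params: NNParamTable | None = None,
    stem_min: int = 3,
    loop_range: tuple[int, int] = (3, 8),
    loop_penalty_dg37: float = 3.5,
    flag_threshold_dg37: float = -3.0,
) -> HairpinResult:
    """Scan a region for two-state stem-loop (hairpin) structures.

    All stems of >= ``stem_min`` Watson-Crick pairs closing a loop of
    ``loop_range`` nt are enumerated; each is scored as the sum of its stem
    stack dG37 values plus a fixed loop penalty.  The region is flagged when
    the most stable candidate falls below ``flag_threshold_dg37``.  This is a
    deliberate simplification of a full secondary-structure fold: no bulges,
    internal loops or multiloops.
    """
    region = region.upper()
    n = len(region)
    if n < 2 * stem_min + loop_range[0]:
        return HairpinResult(worst_dg37=None, flagged=False)
    params = params or NNParamTable.default()
    comp = {"A": "T", "T": "A", "G": "C", "C": "G"}
    best: HairpinResult | None = None
    # enumerate by innermost pair (i, j) and grow the stem outward, so each
    # additional pair only adds one stack to the running score
    for i in range(n):
        for loop in range(loop_range[0], loop_range[1] + 1):
            j = i + loop + 1
            if j >= n:
                break
            dg_stacks = 0.0
            s = 0
            while i - s >= 0 and j + s < n and comp.get(region[i - s]) == region[j + s]:
                if s > 0:
                    # stack between this pair and the previous (inner) one;
                    # partner string is the complement in top-strand order
                    top = region[i - s : i - s + 2]
                    dh, dsv = params.stack(top, comp[top[0]] + comp[top[1]])
                    dg_stacks += dh - T37_K * dsv / 1000.0
                s += 1
                if s >= stem_min:
                    dg = dg_stacks + loop_penalty_dg37
                    if best is None or dg < best.worst_dg37:
                        best = HairpinResult(
                            worst_dg37=dg,
                            flagged=dg < flag_threshold_dg37,
                            stem_bp=s,
                            loop_nt=loop,
                            position=i - s + 2,
                        )
    if best is None:
        return HairpinResult(worst_dg37=None, flagged=False)
    return best


def design_fret_pair(
    locus: SNPLocus,
    constraints: DesignConstraints | None = None,
    buffer: BufferConditions | None = None,
    params: NNParamTable | None = None,
) -> DesignOutcome:
    """End-to-end FRET pair design over both orientations and anchor sides.

    For each probe orientation (plus/minus-matching) and each anchored side,
    the acceptor length scan is run with the fixed end placed so the SNP sits
    centrally at the minimum scanned length; the best qualifying acceptor gets
    a donor placed under the FRET gap constraint, and the probe-binding
    region is screened for hairpins.  The best design (unflagged preferred,
    then maximal dTm) is returned; if no combination works, the outcome
    carries per-stage diagnostics.
    """
    constraints = constraints or DesignConstraints()
    buffer = buffer or BufferConditions()
    l_min = constraints.acceptor_length_range[0]
    lengths = range(constraints.acceptor_length_range[0], constraints.acceptor_length_range[1] + 1)
    half = (l_min - 1) // 2
    candidates: list[ProbePairDesign] = []
    diagnostics: list[str] = []
    for probe_matches in ("plus", "minus"):
        for fixed_end in ("left", "right"):
            if fixed_end == "left":
                anchor = ScanAnchor(locus.snp_position - half, "left", probe_matches)
            else:
                anchor = ScanAnchor(locus.snp_position + half, "right", probe_matches)
            stage = f"[{probe_matches}/{fixed_end}]"
            try:
                scan = length_scan(locus, anchor, lengths, buffer, params)
            except CoverageError as exc:
                diagnostics.append(f"{stage} scan failed: {exc}")
                continue
            chosen = select_acceptor(scan, constraints)
            if chosen is None:
                diagnostics.append(
                    f"{stage} no scan row with dTm >= {constraints.delta_tm_min} degC inside "
                    f"Tm window {constraints.acceptor_tm_window}"
                )
                continue
            acceptor = replace(
                chosen.probe, name="acceptor", label5=ACCEPTOR_DYE, label3=PHOSPHATE_BLOCK
            )
            try:
                donor = place_donor(locus, acceptor, constraints, buffer, params)
            except PlacementError as exc:
                diagnostics.append(f"{stage} donor placement failed: {exc}")
                continue
            if donor.strand == "plus":
                d_start, d_end = donor.anchor, donor.anchor + len(donor) - 1
            else:
                d_start, d_end = donor.anchor - len(donor) + 1, donor.anchor
            a_start, a_end = chosen.footprint
            gap = a_start - d_end - 1 if probe_matches == "plus" else d_start - a_end - 1
            region_lo = max(1, min(d_start, a_start) - 10)
            region_hi = min(len(locus.sequence), max(d_end, a_end) + 10)
            hp = hairpin_screen(locus.sequence[region_lo - 1 : region_hi], params)
            candidates.append(
                ProbePairDesign(
                    donor=donor,
                    acceptor=acceptor,
                    gap_nt=gap,
                    tm_ref=chosen.tm_match,
                    tm_alt=chosen.tm_mismatch,
                    delta_tm=chosen.delta_tm,
                    hairpin_flagged=hp.flagged,
                    hairpin_dg37=hp.worst_dg37,
                    rationale=(
                        f"{stage} acceptor length {chosen.length} nt at {a_start}..{a_end} "
                        f"(Tm match {chosen.tm_match:.2f} degC, mismatch "
                        f"{chosen.tm_mismatch:.2f} degC, dTm {chosen.delta_tm:.2f} degC); "
                        f"donor {len(donor)} nt at {d_start}..{d_end}, gap {gap} nt; "
                        f"hairpin worst dG37 {hp.worst_dg37} kcal/mol"
                        + (" [FLAGGED]" if hp.flagged else "")
                    ),
                    acceptor_footprint=(a_start, a_end),
                    donor_footprint=(d_start, d_end),
                    probe_matches=probe_matches,
                )
            )
    if not candidates:
        return DesignOutcome(design=None, diagnostics=tuple(diagnostics))
    best = min(
        candidates,
        key=lambda d: (d.hairpin_flagged, -d.delta_tm, len(d.acceptor.bases), d.tm_ref),
    )
    return DesignOutcome(design=best, diagnostics=tuple(diagnostics))


def validate_design(
    design: ProbePairDesign,
    locus: SNPLocus,
    constraints: DesignConstraints,
    buffer: BufferConditions,
    params: NNParamTable | None = None,
) -> list[str]:
    """Independent re-check of a returned design against the constraints.

    Recomputes footprint geometry, label bookkeeping and both per-allele Tms
    from scratch; returns a list of violation messages (empty = valid).
    """
    v: list[str] = []
    a_start, a_end = design.acceptor_footprint
    d_start, d_end = design.donor_footprint
    if not (a_start < locus.snp_position < a_end):
        v.append("SNP not strictly inside acceptor footprint")
    if d_start <= locus.snp_position <= d_end:
        v.append("SNP under donor footprint")
    if max(a_start, d_start) <= min(a_end, d_end):
        v.append("donor and acceptor footprints overlap")
    if design.probe_matches == "plus":
        gap = a_start - d_end - 1
    else:
        gap = d_start - a_end - 1
    if gap != design.gap_nt:
        v.append(f"stored gap {design.gap_nt} != geometric gap {gap}")
    if not (constraints.gap_range[0] <= gap <= constraints.gap_range[1]):
        v.append(f"gap {gap} outside range {constraints.gap_range}")
    if design.donor.label3 != DONOR_DYE:
        v.append("donor missing 3' donor dye")
    if design.acceptor.label5 != ACCEPTOR_DYE or design.acceptor.label3 != PHOSPHATE_BLOCK:
        v.append("acceptor missing 5' dye or 3' phosphate block")
    if design.donor.strand != design.acceptor.strand:
        v.append("donor and acceptor on different strands")

    # recompute thermodynamics from the locus
    ref_seq = locus.allele_sequence(locus.ref_allele)
    alt_seq = locus.allele_sequence(locus.alt_allele)
    fp_ref, fp_alt = ref_seq[a_start - 1 : a_end], alt_seq[a_start - 1 : a_end]
    if design.probe_matches == "plus":
        t_ref, t_alt = reverse_complement(fp_ref), reverse_complement(fp_alt)
    else:
        t_ref, t_alt = fp_ref, fp_alt
    tm_ref = duplex_thermo(align_probe(design.acceptor, t_ref, 1), buffer, params).tm_corrected
    tm_alt = duplex_thermo(align_probe(design.acceptor, t_alt, 1), buffer, params).tm_corrected
    if abs(tm_ref - design.tm_ref) > 1e-6 or abs(tm_alt - design.tm_alt) > 1e-6:
        v.append("stored per-allele Tms do not match recomputation")
    if abs((tm_ref - tm_alt) - design.delta_tm) > 1e-6:
        v.append("stored delta_tm does not match recomputation")
    if design.delta_tm < constraints.delta_tm_min:
        v.append(f"delta_tm {design.delta_tm:.2f} below minimum {constraints.delta_tm_min}")
    lo, hi = constraints.acceptor_tm_window
    if not (lo <= tm_ref <= hi):
        v.append(f"acceptor matched Tm {tm_ref:.2f} outside window {constraints.acceptor_tm_window}")
    d_fp = locus.sequence[d_start - 1 : d_end]
    d_target = reverse_complement(d_fp) if design.donor.strand == "plus" else d_fp
    tm_donor = duplex_thermo(align_probe(design.donor, d_target, 1), buffer, params).tm_corrected
    if tm_donor < tm_ref + constraints.donor_minus_acceptor_tm_min - 1e-9:
        v.append(
            f"donor Tm {tm_donor:.2f} below acceptor Tm + margin "
            f"({tm_ref + constraints.donor_minus_acceptor_tm_min:.2f})"
        )
    return v
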