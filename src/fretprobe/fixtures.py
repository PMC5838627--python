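"""Synthetic 480 bp rs1006737-like locus built around the published assay oligos.

The six assay oligonucleotides (two outer primers, two inner primers, donor
and acceptor probe) are pinned at their published coordinates inside a 480 bp
fragment; all other bases are seeded pseudo-random filler screened so that no
oligo has a second exact binding site.  The fragment start maps genomic
coordinate 270121 to offset 1, i.e. offset = genomic position - 270120.

Strand bookkeeping: both probes are plus-strand-matching (their printed
sequences read the fixture's reference strand and they hybridize to its
complement).  This is the orientation under which the printed dye placement
(donor 3' dye, acceptor 5' dye + 3' phosphate) brings the two dyes within
gap+1 nucleotides.  The rs1006737 G/A alleles therefore live on the probe
*target* strand; on the fixture reference strand the SNP reads C (G allele)
or T (A allele).  The SNP sits under the most central acceptor base able to
Watson-Crick-pair a G (probe index 10, fragment offset 231).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import ACCEPTOR_DYE, DONOR_DYE, PHOSPHATE_BLOCK, SNPLocus
from .errors import ValidationError
from .thermo import Oligo, reverse_complement

FRAGMENT_LENGTH = 480
GENOMIC_START = 270121  # genomic coordinate of fragment offset 1
COORD_BASE = GENOMIC_START - 1

#: published oligo set: name -> (sequence 5'->3', genomic position, orientation)
#: positions are the 5'-most reference-strand footprint base for plus oligos
#: and the rightmost footprint base for minus (reverse) oligos
TABLE_OLIGOS: dict[str, tuple[str, int, str]] = {
    "OG644F": ("GGCTTCAGAGTCCACTTGGC", 270271, "plus"),
    "OG645R": ("TGGGCACATTCAAACCTGAA", 270410, "minus"),
    "OG646F": ("CAAAGTCTTGCTATCAATTACATA", 270296, "plus"),
    "OG647R": ("CTGAGAGACACTGTGAGGTC", 270380, "minus"),
    "OG648": ("CATTCCATCTCAGCCC", 270325, "plus"),   # donor probe, 3' fluorescein
    "OG649": ("AAGTGTTTTCAGAGCC", 270342, "plus"),   # acceptor probe, 5' Red640 + 3' P
}

#: fragment offset of the SNP (under acceptor probe index 10)
SNP_OFFSET = 231
#: 1-based index of the SNP inside the acceptor footprint / probe
SNP_PROBE_INDEX = 10
#: reference-strand base per allele (alleles are named on the probe target strand)
ALLELE_TO_REF_BASE = {"G": "C", "A": "T"}

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureLocus:
    """The synthetic fragment for one allele, with oligo footprint bookkeeping."""

    sequence: str
    allele: str
    oligo_map: dict[str, int]  # name -> 1-based fragment offset (anchor convention)
    snp_offset: int  # fragment coordinate of the SNP
    snp_probe_index: int  # 1-based index inside the acceptor footprint

    def snp_locus(self, name: str = "rs1006737-like") -> SNPLocus:
        """SNPLocus on the fixture reference strand (ref = C <-> allele G)."""
        ref_base, alt_base = ALLELE_TO_REF_BASE["G"], ALLELE_TO_REF_BASE["A"]
        seq = self.sequence
        if seq[self.snp_offset - 1] != ref_base:
            seq = seq[: self.snp_offset - 1] + ref_base + seq[self.snp_offset :]
        return SNPLocus(
            sequence=seq,
            snp_position=self.snp_offset,
            ref_allele=ref_base,
            alt_allele=alt_base,
            name=name,
        )

    def footprint(self, name: str) -> tuple[int, int]:
        seq, _, orient = TABLE_OLIGOS[name]
        off = self.oligo_map[name]
        if orient == "plus":
            return off, off + len(seq) - 1
        return off - len(seq) + 1, off

    def oligo(self, name: str) -> Oligo:
        seq, _, orient = TABLE_OLIGOS[name]
        label5 = ACCEPTOR_DYE if name == "OG649" else None
        label3 = {"OG648": DONOR_DYE, "OG649": PHOSPHATE_BLOCK}.get(name)
        return Oligo(
            name=name,
            bases=seq,
            label5=label5,
            label3=label3,
            anchor=self.oligo_map[name],
            strand=orient,
        )

    def acceptor_target(self) -> str:
        """The strand segment the acceptor hybridizes to (5'->3'), this allele."""
        start, end = self.footprint("OG649")
        return reverse_complement(self.sequence[start - 1 : end])


def table_oligo(name: str) -> Oligo:
    """A published oligo with its labels and fragment-offset anchor."""
    seq, pos, orient = TABLE_OLIGOS[name]
    label5 = ACCEPTOR_DYE if name == "OG649" else None
    label3 = {"OG648": DONOR_DYE, "OG649": PHOSPHATE_BLOCK}.get(name)
    return Oligo(
        name=name, bases=seq, label5=label5, label3=label3,
        anchor=pos - COORD_BASE, strand=orient,
    )


def _count_sites(hay: str, needle: str) -> int:
    n, start = 0, 0
    while True:
        i = hay.find(needle, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


def build_fixture(allele: str = "G", seed: int = 1, max_attempts: int = 100) -> FixtureLocus:
    """Deterministically build the synthetic locus for the given allele.

    The filler is pseudo-random with ~50 % GC and is redrawn (up to
    ``max_attempts`` times) until every oligo's binding site is unique on
    both allele variants of the fragment, so primer-uniqueness validation
    stays meaningful.  The same seed yields the same filler for both alleles;
    the two allelic fragments differ at exactly one position.
    """
    allele = allele.upper()
    if allele not in ALLELE_TO_REF_BASE:
        raise ValidationError(f"allele must be 'G' or 'A', got {allele!r}")

    fixed: dict[int, str] = {}  # 0-based fragment index -> base
    oligo_map: dict[str, int] = {}
    for name, (seq, pos, orient) in TABLE_OLIGOS.items():
        off = pos - COORD_BASE
        oligo_map[name] = off
        fp_seq = seq if orient == "plus" else reverse_complement(seq)
        start = off if orient == "plus" else off - len(seq) + 1
        for k, base in enumerate(fp_seq):
            idx = start - 1 + k
            if idx in fixed and fixed[idx] != base:
                raise ValidationError(f"oligo footprints conflict at fragment offset {idx + 1}")
            fixed[idx] = base

    rng = np.random.default_rng(seed)
    free = [i for i in range(FRAGMENT_LENGTH) if i not in fixed]
    for attempt in range(max_attempts):
        draw = _BASES[rng.integers(0, 4, size=len(free))]
        arr = [""] * FRAGMENT_LENGTH
        for i, b in fixed.items():
            arr[i] = b
        for i, b in zip(free, draw):
            arr[i] = str(b)
        ref_variant = "".join(arr)  # carries the printed (G-allele) bases
        alt_variant = (
            ref_variant[: SNP_OFFSET - 1] + ALLELE_TO_REF_BASE["A"] + ref_variant[SNP_OFFSET:]
        )
        ok = True
        for name, (seq, _, orient) in TABLE_OLIGOS.items():
            for variant in (ref_variant, alt_variant):
                hits = _count_sites(variant, seq) + _count_sites(variant, reverse_complement(seq))
                expected = 1
                if name == "OG649" and variant is alt_variant:
                    expected = 0  # acceptor matches exactly only on the G allele
                if hits != expected:
                    ok = False
                    break
            if not ok:
                break
        gc = sum(b in "GC" for b in ref_variant) / FRAGMENT_LENGTH
        if ok and 0.40 <= gc <= 0.60:
            sequence = ref_variant if allele == "G" else alt_variant
            return FixtureLocus(
                sequence=sequence,
                allele=allele,
                oligo_map=oligo_map,
                snp_offset=SNP_OFFSET,
                snp_probe_index=SNP_PROBE_INDEX,
            )
    raise ValidationError(f"could not build a clean fixture in {max_attempts} attempts")
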