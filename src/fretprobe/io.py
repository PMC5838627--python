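"""File I/O: FASTA, SNP specs, oligo/assay-sheet TSV, curve CSV, call JSON."""

from __future__ import annotations

import csv
import json
from dataclasses import asdict

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import ProbePairDesign, SNPLocus
from .errors import ParseError
from .melt import GenotypeCall, MeltingCurve
from .primers import PrimerSet
from .thermo import Oligo

_FASTA_ALPHABET = frozenset("ACGTN")


def read_fasta(path) -> dict[str, str]:
    """Read named DNA sequences; rejects non-ACGTN characters with position."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        for i, base in enumerate(seq, start=1):
            if base not in _FASTA_ALPHABET:
                raise ParseError(
                    f"{path}: record {rec.id!r} has non-ACGTN character {base!r} at position {i}"
                )
        records[rec.id] = seq
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: dict[str, str], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()),
        str(path),
        "fasta",
    )


def read_snp_spec(path, sequence: str, name: str | None = None) -> SNPLocus:
    """Parse a SNP specification against a reference sequence.

    Accepts either a minimal 4-column TSV (name, 1-based position, ref, alt)
    or a VCF-style data line (CHROM POS ID REF ALT ...); ``#`` lines are
    skipped.  The ref allele is validated against the sequence.
    """
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 5 and fields[1].isdigit():  # CHROM POS ID REF ALT
                spec_name, pos, ref, alt = fields[2], fields[1], fields[3], fields[4]
                if spec_name == ".":
                    spec_name = fields[0]
            elif len(fields) == 4:
                spec_name, pos, ref, alt = fields
            else:
                raise ParseError(f"{path}:{lineno}: expected 4 (TSV) or >=5 (VCF-like) columns")
            try:
                position = int(pos)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: position {pos!r} is not an integer") from None
            return SNPLocus(
                sequence=sequence,
                snp_position=position,
                ref_allele=ref,
                alt_allele=alt,
                name=name or spec_name,
            )
    raise ParseError(f"{path}: no SNP specification line found")


_OLIGO_FIELDS = ("name", "bases", "label5", "label3", "anchor", "strand")


def write_oligo_tsv(oligos, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_OLIGO_FIELDS)
        for o in oligos:
            w.writerow(
                [o.name, o.bases, o.label5 or "", o.label3 or "",
                 "" if o.anchor is None else o.anchor, o.strand]
            )


def read_oligo_tsv(path) -> list[Oligo]:
    oligos = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or tuple(reader.fieldnames) != _OLIGO_FIELDS:
            raise ParseError(f"{path}: expected header {_OLIGO_FIELDS}")
        for lineno, row in enumerate(reader, start=2):
            try:
                oligos.append(
                    Oligo(
                        name=row["name"],
                        bases=row["bases"],
                        label5=row["label5"] or None,
                        label3=row["label3"] or None,
                        anchor=int(row["anchor"]) if row["anchor"] else None,
                        strand=row["strand"],
                    )
                )
            except Exception as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return oligos


def write_scan_tsv(scan, path) -> None:
    """Length-scan table: one row per candidate acceptor length."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["length_nt", "tm_match_C", "tm_mismatch_C", "delta_tm_C",
                    "footprint_start", "footprint_end", "probe_5to3"])
        for r in scan.rows:
            w.writerow(
                [r.length, f"{r.tm_match:.4f}", f"{r.tm_mismatch:.4f}", f"{r.delta_tm:.4f}",
                 r.footprint[0], r.footprint[1], r.probe.bases]
            )


def write_assay_sheet(design: ProbePairDesign | None, primers: PrimerSet | None, path) -> None:
    """The assay sheet: every oligo of the design as one TSV row."""
    oligos: list[Oligo] = []
    if design is not None:
        oligos += [design.donor, design.acceptor]
    if primers is not None:
        oligos += list(primers.oligos())
    write_oligo_tsv(oligos, path)


def read_assay_sheet(path) -> dict[str, Oligo]:
    return {o.name: o for o in read_oligo_tsv(path)}


def write_assay_json(design: ProbePairDesign | None, primers: PrimerSet | None, path) -> None:
    payload: dict = {}
    if design is not None:
        payload["probe_pair"] = {
            "donor": asdict(design.donor),
            "acceptor": asdict(design.acceptor),
            "gap_nt": design.gap_nt,
            "tm_ref_C": design.tm_ref,
            "tm_alt_C": design.tm_alt,
            "delta_tm_C": design.delta_tm,
            "hairpin_flagged": design.hairpin_flagged,
            "hairpin_dg37_kcal_mol": design.hairpin_dg37,
            "acceptor_footprint": list(design.acceptor_footprint),
            "donor_footprint": list(design.donor_footprint),
            "rationale": design.rationale,
        }
    if primers is not None:
        payload["nested_primers"] = {
            "outer_amplicon": list(primers.outer_amplicon),
            "inner_amplicon": list(primers.inner_amplicon),
            "outer_amplicon_bp": primers.outer_length,
            "inner_amplicon_bp": primers.inner_length,
            "oligos": {o.name: asdict(o) for o in primers.oligos()},
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_curve_csv(curve: MeltingCurve, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["temperature_C", "bound_fraction", "derivative"])
        for t, b, d in zip(curve.temperatures, curve.bound_fraction, curve.derivative):
            w.writerow([f"{t:.4f}", f"{b:.9f}", f"{d:.9f}"])


def read_curve_csv(path, label: str = "") -> MeltingCurve:
    t, b, d = [], [], []
    with open(path) as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["temperature_C", "bound_fraction", "derivative"]:
            raise ParseError(f"{path}: unexpected curve CSV header {header}")
        for row in reader:
            t.append(float(row[0]))
            b.append(float(row[1]))
            d.append(float(row[2]))
    return MeltingCurve(np.array(t), np.array(b), np.array(d), label=label)


def write_genotype_json(call: GenotypeCall, path) -> None:
    payload = {
        "call": call.call,
        "reason": call.reason,
        "peaks": [asdict(p) for p in call.peaks],
        "evidence": call.evidence,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
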