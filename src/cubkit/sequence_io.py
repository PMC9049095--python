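"""Reading, validating and translating coding sequences.

Coding sequences (CDS) enter the pipeline through :func:`read_fasta`, are
screened by :func:`validate_cds` against the frame / start / stop / ambiguity
rules, and can be translated with :func:`translate`.  The genetic-code
machinery used throughout the package lives here as :class:`GeneticCode`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from functools import cached_property
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "GeneticCode",
    "CodingSequence",
    "QCReport",
    "STANDARD_CODE",
    "read_fasta",
    "validate_cds",
    "translate",
    "apply_qc",
    "write_qc_table",
]

# QC failure reason codes
NOT_MULTIPLE_OF_3 = "NOT_MULTIPLE_OF_3"
NO_START = "NO_START"
NO_STOP = "NO_STOP"
INTERNAL_STOP = "INTERNAL_STOP"
AMBIGUOUS_BASE = "AMBIGUOUS_BASE"
TOO_SHORT = "TOO_SHORT"

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class GeneticCode:
    """A codon translation table plus the degeneracy structure derived from it.

    Parameters
    ----------
    name:
        Human-readable table name.
    codon_to_aa:
        Mapping of the 61 sense codons (DNA alphabet) to one-letter amino
        acids.
    stop_codons:
        The stop codons of the table.
    start_codons:
        Codons accepted as initiation codons by :func:`validate_cds`.  The
        default standard code accepts ATG only; use
        :meth:`with_start_codons` for a permissive variant.
    """

    name: str
    codon_to_aa: Mapping[str, str]
    stop_codons: frozenset[str]
    start_codons: tuple[str, ...] = ("ATG",)

    @cached_property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(sorted(self.codon_to_aa))

    @cached_property
    def families(self) -> dict[str, tuple[str, ...]]:
        """Amino acid -> sorted tuple of its synonymous codons (all sizes)."""
        fam: dict[str, list[str]] = {}
        for codon, aa in self.codon_to_aa.items():
            fam.setdefault(aa, []).append(codon)
        return {aa: tuple(sorted(cs)) for aa, cs in fam.items()}

    @cached_property
    def degenerate_families(self) -> dict[str, tuple[str, ...]]:
        """Families with two or more synonymous codons."""
        return {aa: cs for aa, cs in self.families.items() if len(cs) > 1}

    @cached_property
    def degenerate_codons(self) -> tuple[str, ...]:
        """Sorted codons of all degenerate families (59 in the standard code)."""
        out = [c for cs in self.degenerate_families.values() for c in cs]
        return tuple(sorted(out))

    @cached_property
    def degeneracy_classes(self) -> dict[int, tuple[str, ...]]:
        """Family size -> amino acids in that class (e.g. 6 -> (L, R, S))."""
        classes: dict[int, list[str]] = {}
        for aa, cs in self.degenerate_families.items():
            classes.setdefault(len(cs), []).append(aa)
        return {k: tuple(sorted(v)) for k, v in sorted(classes.items())}

    def family_of(self, codon: str) -> str:
        return self.codon_to_aa[codon]

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def with_start_codons(self, starts: Iterable[str]) -> "GeneticCode":
        return replace(self, start_codons=tuple(starts))


def _standard_code() -> GeneticCode:
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    table = unambiguous_dna_by_id[1]
    return GeneticCode(
        name="standard",
        codon_to_aa=dict(table.forward_table),
        stop_codons=frozenset(table.stop_codons),
        start_codons=("ATG",),
    )


#: The standard nuclear genetic code (61 sense codons, TAA/TAG/TGA stops).
STANDARD_CODE = _standard_code()


@dataclass(frozen=True)
class QCReport:
    """Outcome of CDS validation; ``valid`` is true iff ``failures`` is empty."""

    failures: tuple[str, ...] = ()

    @property
    def valid(self) -> bool:
        return not self.failures


@dataclass(frozen=True)
class CodingSequence:
    """One coding sequence: identifier, uppercase DNA string, QC status."""

    id: str
    sequence: str
    qc: QCReport | None = None

    def __len__(self) -> int:
        return len(self.sequence)

    def codons(self) -> list[str]:
        """In-frame codons over the full length (truncated tail dropped)."""
        s = self.sequence
        return [s[i : i + 3] for i in range(0, len(s) - len(s) % 3, 3)]

    def sense_codons(self, code: GeneticCode = STANDARD_CODE) -> list[str]:
        """In-frame codons with the terminal stop (if any) removed."""
        cods = self.codons()
        if cods and code.is_stop(cods[-1]):
            cods = cods[:-1]
        return cods


def read_fasta(path: str | os.PathLike) -> list[CodingSequence]:
    """Read a multi-FASTA file into :class:`CodingSequence` records.

    Sequences are uppercased and U (RNA spelling) is mapped to T.  Record
    ids are the first whitespace-delimited header token; order is preserved.
    QC is *not* applied here.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    records = []
    for i, rec in enumerate(SeqIO.parse(path, "fasta")):
        if not rec.id:
            raise ValueError(f"malformed header at record {i + 1} in {path!r}")
        seq = str(rec.seq).upper().replace("U", "T")
        records.append(CodingSequence(id=rec.id, sequence=seq))
    if not records:
        raise ValueError(f"no sequences in {path!r}")
    return records


def validate_cds(
    seq: CodingSequence,
    code: GeneticCode = STANDARD_CODE,
    min_codons: int = 30,
) -> QCReport:
    """Check the CDS validity rules and report *all* applicable failures.

    A valid CDS has length divisible by 3, begins with a configured
    initiation codon, ends with a stop codon, contains no internal stop and
    no ambiguous base, and has at least ``min_codons`` sense codons.
    """
    s = seq.sequence
    if not s:
        raise ValueError(f"empty sequence for {seq.id!r}")
    failures: list[str] = []
    if len(s) % 3 != 0:
        failures.append(NOT_MULTIPLE_OF_3)
    if set(s) - _BASES:
        failures.append(AMBIGUOUS_BASE)
    cods = seq.codons()
    if not cods or cods[0] not in code.start_codons:
        failures.append(NO_START)
    has_terminal_stop = bool(cods) and code.is_stop(cods[-1])
    if not has_terminal_stop:
        failures.append(NO_STOP)
    body = cods[:-1] if has_terminal_stop else cods
    if any(code.is_stop(c) for c in body):
        failures.append(INTERNAL_STOP)
    if len(body) < min_codons:
        failures.append(TOO_SHORT)
    return QCReport(failures=tuple(failures))


def translate(seq: CodingSequence, code: GeneticCode = STANDARD_CODE) -> str:
    """Translate a valid CDS; the terminal stop is dropped.

    Raises ``ValueError`` naming the 1-based codon index on an internal stop.
    """
    protein = []
    for i, codon in enumerate(seq.sense_codons(code), start=1):
        if code.is_stop(codon):
            raise ValueError(
                f"internal stop codon {codon} at codon {i} in {seq.id!r}"
            )
        try:
            protein.append(code.codon_to_aa[codon])
        except KeyError:
            raise ValueError(
                f"untranslatable codon {codon!r} at codon {i} in {seq.id!r}"
            ) from None
    return "".join(protein)


def apply_qc(
    seqs: Sequence[CodingSequence],
    code: GeneticCode = STANDARD_CODE,
    min_codons: int = 30,
    strict: bool = True,
) -> tuple[list[CodingSequence], list[CodingSequence]]:
    """Attach QC reports and split records into (passed, failed).

    Under ``strict`` (default) failed records are excluded from downstream
    statistics; with ``strict=False`` only records whose sole problems are
    ambiguity/short-length are admitted (their N-containing codons are later
    skipped from counts), while frame/start/stop violations always exclude.
    """
    passed, failed = [], []
    hard = {NOT_MULTIPLE_OF_3, NO_START, NO_STOP, INTERNAL_STOP}
    for s in seqs:
        qc = validate_cds(s, code, min_codons)
        s = replace(s, qc=qc)
        if qc.valid:
            passed.append(s)
        elif not strict and not (set(qc.failures) & hard):
            passed.append(s)
        else:
            failed.append(s)
    return passed, failed


def write_qc_table(seqs: Iterable[CodingSequence], path: str | os.PathLike) -> None:
    """Write the QC report as TSV: gene_id, valid, semicolon-joined failures."""
    with open(path, "w") as fh:
        fh.write("gene_id\tvalid\tfailures\n")
        for s in seqs:
            qc = s.qc if s.qc is not None else QCReport()
            fh.write(f"{s.id}\t{str(qc.valid).lower()}\t{';'.join(qc.failures)}\n")
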