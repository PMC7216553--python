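"""Readers and writers for genotype tables, locus panels and FASTA.

Genotype tables are plain TSV (default) or CSV with header columns
``individual_id, population, species, locus, allele1, allele2``
(``mt_haplotype`` optional).  Each allele field uses a fixed-order
mini-syntax so that write → read round-trips are bit-exact::

    tracts=10,9;snps=A,-,T
    id=3;src=maternal_sp;tracts=10;snps=C,A

Segments: optional ``id=`` (catalog label) and ``src=`` (source species),
then ``tracts=`` (comma-separated repeat counts, ordered as the locus's
``variable_tracts``) and ``snps=`` (states ordered as ``snp_positions``;
``-`` is the gap state).  An optional ``seq=`` segment carries a raw
nucleotide sequence.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from Bio import SeqIO

from .core import (
    AlleleRecord,
    Cohort,
    Individual,
    LocusDef,
    SatcloneError,
    Species,
    UnphasedGenotype,
)

PathLike = Union[str, Path]

GENOTYPE_COLUMNS = ["individual_id", "population", "species", "locus", "allele1", "allele2"]


class TableSchemaError(SatcloneError):
    """The file's header does not match the expected schema."""


class TableParseError(SatcloneError):
    """A data row could not be interpreted; the message names the row."""


def _delimiter(path: PathLike, fmt: Optional[str]) -> str:
    if fmt is None:
        fmt = "csv" if str(path).lower().endswith(".csv") else "tsv"
    if fmt not in ("tsv", "csv"):
        raise ValueError(f"format must be 'tsv' or 'csv', got {fmt!r}")
    return "," if fmt == "csv" else "\t"


def format_allele(allele: AlleleRecord, locus: LocusDef) -> str:
    """Serialize an allele in the documented fixed-order mini-syntax."""
    allele.validate_against(locus)
    parts = []
    if allele.allele_id is not None:
        parts.append(f"id={allele.allele_id}")
    if allele.source_species is not None:
        parts.append(f"src={allele.source_species.value}")
    tracts = ",".join(str(allele.tract_lengths[t]) for t in locus.variable_tracts)
    snps = ",".join(allele.snp_profile[s] for s in locus.snp_positions)
    parts.append(f"tracts={tracts}")
    parts.append(f"snps={snps}")
    if allele.sequence is not None:
        parts.append(f"seq={allele.sequence}")
    return ";".join(parts)


def parse_allele(text: str, locus: LocusDef) -> AlleleRecord:
    """Parse the mini-syntax produced by :func:`format_allele`."""
    fields: dict[str, str] = {}
    for seg in text.strip().split(";"):
        if not seg:
            continue
        if "=" not in seg:
            raise TableParseError(f"malformed allele segment {seg!r} in {text!r}")
        k, _, v = seg.partition("=")
        if k in fields:
            raise TableParseError(f"duplicate segment {k!r} in allele {text!r}")
        fields[k] = v
    unknown = set(fields) - {"id", "src", "tracts", "snps", "seq"}
    if unknown:
        raise TableParseError(f"unknown allele segments {sorted(unknown)} in {text!r}")
    if "tracts" not in fields or "snps" not in fields:
        raise TableParseError(f"allele {text!r} lacks tracts=/snps= segments")

    tract_vals = [v for v in fields["tracts"].split(",") if v != ""]
    if len(tract_vals) != len(locus.variable_tracts):
        raise TableParseError(
            f"allele {text!r}: {len(tract_vals)} tract lengths, "
            f"locus {locus.name} defines {len(locus.variable_tracts)}"
        )
    try:
        tracts = {t: int(v) for t, v in zip(locus.variable_tracts, tract_vals)}
    except ValueError as exc:
        raise TableParseError(f"non-integer tract length in {text!r}") from exc

    snp_vals = [v for v in fields["snps"].split(",") if v != ""]
    if len(snp_vals) != len(locus.snp_positions):
        raise TableParseError(
            f"allele {text!r}: {len(snp_vals)} SNP states, "
            f"locus {locus.name} defines {len(locus.snp_positions)}"
        )
    snps = dict(zip(locus.snp_positions, snp_vals))

    src = Species(fields["src"]) if "src" in fields else None
    try:
        return AlleleRecord(
            locus=locus.name,
            tract_lengths=tracts,
            snp_profile=snps,
            allele_id=fields.get("id"),
            source_species=src,
            sequence=fields.get("seq"),
        )
    except ValueError as exc:
        raise TableParseError(f"invalid allele {text!r}: {exc}") from exc


def read_genotype_table(
    path: PathLike, loci: Sequence[LocusDef], fmt: Optional[str] = None
) -> Cohort:
    """Read a genotype table into a :class:`Cohort`.

    Raises :class:`TableSchemaError` for missing columns and
    :class:`TableParseError` for malformed rows (the message carries the
    1-based data row number).
    """
    delim = _delimiter(path, fmt)
    locus_map = {l.name: l for l in loci}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        missing = [c for c in GENOTYPE_COLUMNS if c not in header]
        if missing:
            raise TableSchemaError(f"{path}: missing columns {missing}")
        has_mt = "mt_haplotype" in header

        individuals: dict[str, Individual] = {}
        species_seen: set[Species] = set()
        for rownum, row in enumerate(reader, start=1):
            locus_name = row["locus"]
            if locus_name not in locus_map:
                raise TableParseError(
                    f"{path} row {rownum}: unknown locus {locus_name!r}"
                )
            locus = locus_map[locus_name]
            try:
                species = Species(row["species"])
            except ValueError as exc:
                raise TableParseError(
                    f"{path} row {rownum}: unknown species {row['species']!r}"
                ) from exc
            species_seen.add(species)
            try:
                a1 = parse_allele(row["allele1"], locus)
                a2 = parse_allele(row["allele2"], locus)
            except TableParseError as exc:
                raise TableParseError(f"{path} row {rownum}: {exc}") from exc

            ind_id = row["individual_id"]
            ind = individuals.get(ind_id)
            if ind is None:
                mt = row.get("mt_haplotype") or None if has_mt else None
                ind = Individual(ind_id, row["population"], species, {}, mt)
                individuals[ind_id] = ind
            if locus_name in ind.genotypes:
                raise TableParseError(
                    f"{path} row {rownum}: duplicate genotype for "
                    f"({ind_id}, {locus_name})"
                )
            ind.genotypes[locus_name] = UnphasedGenotype(ind_id, locus_name, (a1, a2))

        if len(species_seen) > 1:
            raise TableParseError(
                f"{path}: mixed species in one table: {sorted(s.value for s in species_seen)}"
            )
        species = species_seen.pop() if species_seen else Species.PARTHENOGEN
    return Cohort(species=species, individuals=list(individuals.values()), loci=list(loci))


def write_genotype_table(cohort: Cohort, path: PathLike, fmt: Optional[str] = None) -> None:
    """Write a cohort as a genotype table readable by :func:`read_genotype_table`."""
    delim = _delimiter(path, fmt)
    locus_map = {l.name: l for l in cohort.loci}
    columns = GENOTYPE_COLUMNS + ["mt_haplotype"]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(columns)
        for ind in cohort.individuals:
            for locus_name in cohort.locus_names:
                g = ind.genotypes.get(locus_name)
                if g is None:
                    continue
                locus = locus_map[locus_name]
                writer.writerow(
                    [
                        ind.individual_id,
                        ind.population,
                        ind.species.value,
                        locus_name,
                        format_allele(g.alleles[0], locus),
                        format_allele(g.alleles[1], locus),
                        ind.mt_haplotype or "",
                    ]
                )


LOCUS_COLUMNS = ["name", "motif", "tracts", "snps"]


def read_locus_table(path: PathLike, fmt: Optional[str] = None) -> list[LocusDef]:
    """Read locus definitions (columns: name, motif, tracts, snps; comma lists)."""
    delim = _delimiter(path, fmt)
    loci = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        missing = [c for c in LOCUS_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise TableSchemaError(f"{path}: missing columns {missing}")
        for row in reader:
            tracts = tuple(t for t in row["tracts"].split(",") if t)
            snps = tuple(s for s in row["snps"].split(",") if s)
            loci.append(LocusDef(row["name"], row["motif"], tracts, snps))
    return loci


def write_locus_table(loci: Sequence[LocusDef], path: PathLike, fmt: Optional[str] = None) -> None:
    delim = _delimiter(path, fmt)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        writer.writerow(LOCUS_COLUMNS)
        for l in loci:
            writer.writerow([l.name, l.motif, ",".join(l.variable_tracts), ",".join(l.snp_positions)])


def read_fasta(path: PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n{seq}\n")
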