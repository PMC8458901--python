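"""File-format helpers: FASTA, BED intervals, VCF SNVs, association tables.

Genomes are passed around as any mapping from contig name to sequence —
a plain ``dict`` of strings (as produced by the simulator) or a
``pyfaidx.Fasta``. :func:`fetch` abstracts over the two. All in-memory
coordinates are 0-based half-open; VCF positions are converted at this
boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

Interval = tuple[str, int, int]


def fetch(genome, chrom: str, start: int, end: int) -> str:
    """Subsequence ``[start, end)`` of a contig from a dict or pyfaidx genome."""
    return str(genome[chrom][start:end])


def contig_lengths(genome) -> dict[str, int]:
    return {name: len(genome[name]) for name in genome.keys()}


def read_fasta(path) -> "pyfaidx.Fasta":
    import pyfaidx

    return pyfaidx.Fasta(str(path))


def write_fasta(genome: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path) -> list[Interval]:
    intervals = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            intervals.append((f[0], int(f[1]), int(f[2])))
    return intervals


def write_bed(intervals, path, names=None) -> None:
    with open(path, "w") as fh:
        for i, (chrom, start, end) in enumerate(intervals):
            name = f"\t{names[i]}" if names is not None else ""
            fh.write(f"{chrom}\t{start}\t{end}{name}\n")


@dataclass(frozen=True)
class SnvRecord:
    """A bi-allelic single-nucleotide substitution.

    ``pos`` is the 0-based position of the substituted base; ``ref`` must
    match the genome base there (checked when a genome is supplied at load).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str = "."

    def __post_init__(self) -> None:
        if self.ref not in "ACGT" or self.alt not in "ACGT":
            raise ValueError(f"ref/alt must be single ACGT bases: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt ({self.ref}) for {self.id}")
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")


def read_snvs_vcf(path, genome=None) -> list[SnvRecord]:
    """Load SNVs from a VCF via cyvcf2.

    Multi-allelic records are decomposed into one record per alternate
    allele; indels/MNVs are skipped with a logged count. With ``genome``
    given, a reference-allele mismatch raises.
    """
    from cyvcf2 import VCF

    records: list[SnvRecord] = []
    skipped = 0
    for v in VCF(str(path)):
        for alt in v.ALT:
            if len(v.REF) != 1 or len(alt) != 1 or v.REF == alt:
                skipped += 1
                continue
            if v.REF not in "ACGT" or alt not in "ACGT":
                skipped += 1
                continue
            pos0 = v.POS - 1
            if genome is not None:
                base = fetch(genome, v.CHROM, pos0, pos0 + 1).upper()
                if base != v.REF:
                    raise ValueError(
                        f"reference mismatch at {v.CHROM}:{v.POS}: "
                        f"VCF says {v.REF}, genome has {base}"
                    )
            records.append(
                SnvRecord(chrom=v.CHROM, pos=pos0, ref=v.REF, alt=alt, id=v.ID or ".")
            )
    if skipped:
        logger.info("skipped %d non-SNV allele(s) while reading %s", skipped, path)
    return records


def write_snvs_vcf(snvs: list[SnvRecord], path, contigs: dict[str, int] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=motifimpact\n")
        for name, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sorted(snvs, key=lambda s: (s.chrom, s.pos)):
            fh.write(f"{s.chrom}\t{s.pos + 1}\t{s.id}\t{s.ref}\t{s.alt}\t.\t.\t.\n")


ASSOC_COLUMNS = ["snv_id", "chrom", "pos", "p_value", "trait"]


def read_associations(path) -> pd.DataFrame:
    """Variant-trait association table: snv_id, chrom, pos (0-based), p_value, trait."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(ASSOC_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"association table missing columns: {sorted(missing)}")
    if (df["p_value"] <= 0).any():
        raise ValueError("association p_values must be > 0")
    return df[ASSOC_COLUMNS]


def write_associations(df: pd.DataFrame, path) -> None:
    df[ASSOC_COLUMNS].to_csv(path, sep="\t", index=False)
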