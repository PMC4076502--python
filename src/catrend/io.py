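"""File readers and writers for genotype count tables and results.

Two input layouts are supported:

* wide counts file — one SNP per row with the header
  ``snp, case_AA, case_Aa, case_aa, ctrl_AA, ctrl_Aa, ctrl_aa``
  (TSV or CSV).  Columns are in the fixed genotype order (AA, Aa, aa)
  with ``a`` the minor allele; the reader never guesses allele
  orientation — use ``flip=True`` to reverse the coding explicitly.
* long per-individual file — columns ``sample, phenotype, genotype`` with
  phenotype in {0, 1} (1 = case) and genotype in {0, 1, 2} = count of the
  minor allele; rows with a missing-genotype token are dropped (and
  counted in the log).

No VCF/PLINK ingestion: the method consumes one 2x3 table per SNP.
Producing the counts file from upstream tools amounts to tabulating
per-genotype sample counts by case status (e.g. ``plink --model`` or a
groupby over a genotype matrix) with the minor allele oriented as above.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

from .tables import GenotypeTable, ValidationError, make_table

logger = logging.getLogger("catrend")

COUNTS_HEADER = ["snp", "case_AA", "case_Aa", "case_aa",
                 "ctrl_AA", "ctrl_Aa", "ctrl_aa"]


def _parse_count(token: str, path: str, line: int, column: str) -> int:
    token = token.strip()
    try:
        value = int(token)
    except ValueError:
        raise ValidationError(
            f"{path}:{line}: column {column!r}: {token!r} is not a "
            "non-negative integer"
        )
    if value < 0:
        raise ValidationError(
            f"{path}:{line}: column {column!r}: negative count {value}"
        )
    return value


def read_counts(
    path: str | Path, dialect: str = "wide_tsv", flip: bool = False
) -> list[tuple[str, GenotypeTable]]:
    """Read a wide counts file; returns one (snp id, table) per data row.

    ``dialect`` is ``wide_tsv`` or ``csv``.  ``flip`` reverses the genotype
    column order of both arms (use when the file's allele orientation is
    opposite to minor-allele coding).
    """
    path = str(path)
    delim = {"wide_tsv": "\t", "csv": ","}.get(dialect)
    if delim is None:
        raise ValidationError(f"unknown dialect {dialect!r}")
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delim)
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty file (no header)")
        header = [h.strip() for h in header]
        if header != COUNTS_HEADER:
            raise ValidationError(
                f"{path}:1: malformed header {header!r}; expected {COUNTS_HEADER!r}"
            )
        out: list[tuple[str, GenotypeTable]] = []
        for i, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 7:
                raise ValidationError(
                    f"{path}:{i}: expected 7 fields, found {len(row)}"
                )
            snp = row[0].strip()
            counts = [
                _parse_count(tok, path, i, col)
                for tok, col in zip(row[1:], COUNTS_HEADER[1:])
            ]
            if flip:
                counts = counts[2::-1] + counts[:2:-1]
            try:
                table = make_table(*counts)
            except ValidationError as exc:
                raise ValidationError(f"{path}:{i}: {exc}")
            out.append((snp, table))
    if not out:
        logger.warning("%s: no data rows found", path)
    return out


def read_individuals(
    path: str | Path,
    snp_id: str = "SNP",
    missing: str = "NA",
    delimiter: str = "\t",
) -> list[tuple[str, GenotypeTable]]:
    """Collapse a per-individual file (sample, phenotype, genotype) to counts.

    Individuals whose genotype equals the ``missing`` token are dropped with
    a logged count.  Phenotype must be 0 (control) or 1 (case); genotype
    0/1/2 counts copies of the minor allele.
    """
    path = str(path)
    cases = [0, 0, 0]
    controls = [0, 0, 0]
    dropped = 0
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        header = next(reader, None)
        if header is None:
            raise ValidationError(f"{path}: empty file (no header)")
        for i, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 3:
                raise ValidationError(
                    f"{path}:{i}: expected 3 fields (sample, phenotype, genotype)"
                )
            pheno_tok, geno_tok = row[1].strip(), row[2].strip()
            if pheno_tok not in ("0", "1"):
                raise ValidationError(
                    f"{path}:{i}: phenotype {pheno_tok!r} is not 0 or 1"
                )
            if geno_tok == missing:
                dropped += 1
                continue
            if geno_tok not in ("0", "1", "2"):
                raise ValidationError(
                    f"{path}:{i}: genotype {geno_tok!r} is not 0, 1, 2, "
                    f"or the missing token {missing!r}"
                )
            arm = cases if pheno_tok == "1" else controls
            arm[int(geno_tok)] += 1
    if dropped:
        logger.warning("%s: dropped %d individuals with missing genotype",
                       path, dropped)
    if sum(cases) + sum(controls) == 0:
        raise ValidationError(f"{path}: no usable records")
    try:
        table = make_table(*cases, *controls)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}")
    return [(snp_id, table)]


def format_results_tsv(rows: list[dict]) -> str:
    """Render result records as TSV at full double precision."""
    if not rows:
        return ""
    cols = list(rows[0].keys())
    lines = ["\t".join(cols)]
    for row in rows:
        rendered = []
        for c in cols:
            v = row[c]
            rendered.append(f"{v:.17g}" if isinstance(v, float) else str(v))
        lines.append("\t".join(rendered))
    return "\n".join(lines) + "\n"
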