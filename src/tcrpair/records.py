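"""Parsing, validation and normalization of tabular TCR-pMHC pair data.

The internal schema mirrors the public curated TCR-specificity databases
(McPAS-TCR, VDJdb): one row per observed TCR-peptide pair with the CDR3
sequences of both chains, V/J gene calls, the presenting MHC allele, the
T-cell compartment (CD4/CD8) and a binary binding label. Column headers of
a source table are mapped onto this schema by a small dialect descriptor so
differently-named exports all normalize to the same records.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: sentinel for any field that is absent / unknown in the source table
ABSENT = ""

#: table cell values that normalize to ABSENT (case-insensitive)
MISSING_TOKENS = frozenset({"", "na", "n/a", "nan", "none", "unknown", "-"})

CANONICAL_COLUMNS = (
    "cdr3_beta", "cdr3_alpha", "v_beta", "j_beta", "v_alpha", "j_alpha",
    "mhc", "t_cell_type", "peptide", "label",
)

CATEGORICAL_FIELDS = ("v_beta", "j_beta", "v_alpha", "j_alpha", "mhc")

#: built-in header dialects for the two common database exports
DIALECTS: dict[str, dict[str, str]] = {
    "canonical": {c: c for c in CANONICAL_COLUMNS},
    "mcpas": {
        "CDR3.beta.aa": "cdr3_beta",
        "CDR3.alpha.aa": "cdr3_alpha",
        "TRBV": "v_beta",
        "TRBJ": "j_beta",
        "TRAV": "v_alpha",
        "TRAJ": "j_alpha",
        "MHC": "mhc",
        "T.Cell.Type": "t_cell_type",
        "Epitope.peptide": "peptide",
        "Label": "label",
    },
    "vdjdb": {
        "cdr3.beta": "cdr3_beta",
        "cdr3.alpha": "cdr3_alpha",
        "v.beta": "v_beta",
        "j.beta": "j_beta",
        "v.alpha": "v_alpha",
        "j.alpha": "j_alpha",
        "mhc.a": "mhc",
        "t.cell.type": "t_cell_type",
        "antigen.epitope": "peptide",
        "label": "label",
    },
}


class SchemaError(ValueError):
    """Raised when a table's headers cannot be mapped onto the schema."""


@dataclass(frozen=True)
class PairRecord:
    """One TCR-pMHC observation.

    ``cdr3_beta`` and ``peptide`` are always present; every other field may
    be :data:`ABSENT`. ``label`` is 1 for a binding pair, 0 for a sampled
    non-binding pair.
    """

    cdr3_beta: str
    peptide: str
    label: int = 1
    cdr3_alpha: str = ABSENT
    v_beta: str = ABSENT
    j_beta: str = ABSENT
    v_alpha: str = ABSENT
    j_alpha: str = ABSENT
    mhc: str = ABSENT
    t_cell_type: str = ABSENT  # "CD4", "CD8" or ABSENT

    def has_alpha(self) -> bool:
        return self.cdr3_alpha != ABSENT

    def tcr_side(self) -> tuple:
        """The fields inherited from the TCR partner during negative sampling."""
        return (self.cdr3_beta, self.cdr3_alpha, self.v_beta, self.j_beta,
                self.v_alpha, self.j_alpha, self.t_cell_type)

    def pmhc_side(self) -> tuple:
        return (self.peptide, self.mhc)

    def validate(self) -> None:
        if not validate_amino_sequence(self.cdr3_beta):
            raise ValueError(f"invalid CDR3beta sequence: {self.cdr3_beta!r}")
        if not validate_amino_sequence(self.peptide):
            raise ValueError(f"invalid peptide sequence: {self.peptide!r}")
        if self.cdr3_alpha != ABSENT and not validate_amino_sequence(self.cdr3_alpha):
            raise ValueError(f"invalid CDR3alpha sequence: {self.cdr3_alpha!r}")
        if self.cdr3_alpha == ABSENT and (self.v_alpha != ABSENT or self.j_alpha != ABSENT):
            raise ValueError("alpha V/J genes present without a CDR3alpha sequence")
        if self.t_cell_type not in (ABSENT, "CD4", "CD8"):
            raise ValueError(f"t_cell_type must be CD4/CD8/absent, got {self.t_cell_type!r}")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


def validate_amino_sequence(seq: str) -> bool:
    """True iff ``seq`` is non-empty and uses only the 20 canonical residues."""
    return bool(seq) and all(c in _AA_SET for c in seq)


def normalize_cell(value: str | None) -> str:
    if value is None or value.strip().lower() in MISSING_TOKENS:
        return ABSENT
    return value.strip()


def parse_table(path: str | Path, dialect: str | dict[str, str] = "canonical",
                delimiter: str | None = None) -> list[PairRecord]:
    """Read a CSV/TSV of TCR-peptide pairs into validated records.

    Rows lacking a usable CDR3beta or peptide are dropped (with a logged
    count) rather than treated as errors; a row whose alpha-chain genes
    appear without an alpha CDR3 keeps the genes but is only consistent once
    the genes are cleared, so those genes are dropped too.

    Parameters
    ----------
    dialect:
        Name of a built-in header mapping (``canonical``, ``mcpas``,
        ``vdjdb``) or an explicit ``{source_header: canonical_name}`` dict.
    """
    path = Path(path)
    if isinstance(dialect, str):
        try:
            mapping = DIALECTS[dialect]
        except KeyError:
            raise SchemaError(f"unknown dialect {dialect!r}") from None
    else:
        mapping = dict(dialect)
    unknown = set(mapping.values()) - set(CANONICAL_COLUMNS)
    if unknown:
        raise SchemaError(f"dialect maps to unknown schema columns: {sorted(unknown)}")

    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","

    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, no header row")
        header = set(reader.fieldnames)
        required_sources = [src for src, dst in mapping.items()
                            if dst in ("cdr3_beta", "peptide")]
        for src in required_sources:
            if src not in header:
                raise SchemaError(f"{path}: required column {src!r} not in header")
        rows = list(reader)

    records: list[PairRecord] = []
    n_dropped = 0
    for row in rows:
        values = {dst: normalize_cell(row.get(src)) for src, dst in mapping.items()
                  if src in header}
        beta = values.get("cdr3_beta", ABSENT).upper()
        pep = values.get("peptide", ABSENT).upper()
        if not validate_amino_sequence(beta) or not validate_amino_sequence(pep):
            n_dropped += 1
            continue
        alpha = values.get("cdr3_alpha", ABSENT).upper()
        if not validate_amino_sequence(alpha):
            alpha = ABSENT
        t_type = values.get("t_cell_type", ABSENT).upper()
        if t_type not in ("CD4", "CD8"):
            t_type = ABSENT
        raw_label = values.get("label", ABSENT)
        label = 1 if raw_label in (ABSENT, "1", "bind", "True", "TRUE") else 0
        rec = PairRecord(
            cdr3_beta=beta, peptide=pep, label=label, cdr3_alpha=alpha,
            v_beta=values.get("v_beta", ABSENT),
            j_beta=values.get("j_beta", ABSENT),
            v_alpha=values.get("v_alpha", ABSENT) if alpha else ABSENT,
            j_alpha=values.get("j_alpha", ABSENT) if alpha else ABSENT,
            mhc=values.get("mhc", ABSENT),
            t_cell_type=t_type,
        )
        rec.validate()
        records.append(rec)
    if n_dropped:
        logger.info("parse_table(%s): dropped %d rows lacking CDR3beta or peptide",
                    path.name, n_dropped)
    return records


def write_table(records: list[PairRecord], path: str | Path) -> None:
    """Write records as canonical CSV (round-trips through parse_table)."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CANONICAL_COLUMNS)
        for r in records:
            writer.writerow([getattr(r, c) for c in CANONICAL_COLUMNS])


def deduplicate(records: list[PairRecord]) -> list[PairRecord]:
    """Drop exact duplicates (identical on every field), keeping first seen."""
    seen: set[PairRecord] = set()
    out = []
    for r in records:
        if r not in seen:
            seen.add(r)
            out.append(r)
    return out


@dataclass
class Vocabulary:
    """Categorical value -> embedding-row index with a reserved unknown row.

    Every distinct value seen in training receives its own index; gene names
    are never grouped or prefix-merged (TRAV9, TRAV9-1 and TRAV9-3 are three
    entries) and MHC strings are kept verbatim (HLA-A*02 and HLA-A*02:01
    differ). Any value never seen in training -- including an absent value --
    resolves to ``unknown_index``.
    """

    field_name: str
    index_of: dict[str, int] = field(default_factory=dict)
    unknown_index: int = 0

    def __len__(self) -> int:
        return len(self.index_of) + 1

    def lookup(self, value: str) -> int:
        if value == ABSENT:
            return self.unknown_index
        return self.index_of.get(value, self.unknown_index)

    def to_json(self) -> str:
        return json.dumps({"field_name": self.field_name,
                           "unknown_index": self.unknown_index,
                           "index_of": self.index_of}, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Vocabulary":
        d = json.loads(text)
        return cls(field_name=d["field_name"], index_of=d["index_of"],
                   unknown_index=d["unknown_index"])


def build_vocabulary(records: list[PairRecord], field_name: str) -> Vocabulary:
    """Index every distinct present value of a categorical field.

    Index 0 is reserved for the unknown symbol; observed values occupy
    1..n in first-seen order, so indices are contiguous and deterministic
    for a fixed record order.
    """
    if field_name not in CATEGORICAL_FIELDS:
        raise ValueError(f"{field_name!r} is not a categorical field")
    index_of: dict[str, int] = {}
    for r in records:
        v = getattr(r, field_name)
        if v != ABSENT and v not in index_of:
            index_of[v] = len(index_of) + 1
    return Vocabulary(field_name=field_name, index_of=index_of, unknown_index=0)
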