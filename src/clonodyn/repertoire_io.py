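"""Domain types and I/O for bulk TCR-beta repertoires.

A *clone* (clonotype) is a rearranged TCR-beta sequence identified by its
CDR3 nucleotide junction plus V and J gene calls, carrying a template count:
the number of input DNA molecules attributed to the rearrangement by the
immunosequencing assay. A *repertoire* is one sample's collection of clones
with its subject / timepoint / compartment metadata.

Two tabular dialects are supported: the AIRR Rearrangement TSV (read and
written) and the ImmunoSEQ export TSV (read only, via a versioned column
mapping).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import pandas as pd

from clonodyn.errors import FormatError, RowParseError, UndefinedStatisticError

logger = logging.getLogger(__name__)

#: Ordered treatment-schedule timepoints: baseline, cycle-1 day-8, and
#: end-of-cycle samples every other cycle.
DEFAULT_TIMEPOINT_ORDER = ("Day0", "C1D8", "EOC2", "EOC4", "EOC6", "EOC8")

#: Sampled tissue compartments: bone marrow, peripheral blood, and
#: bead-enriched CD8+ T cells.
COMPARTMENTS = ("BM", "PB", "sortedCD8")

_ALLELE_RE = re.compile(r"\*\d+$")
_CDR3_NT_RE = re.compile(r"^[ACGTN]*$")

AIRR_COLUMNS = ("junction", "junction_aa", "v_call", "j_call", "duplicate_count", "productive")

#: ImmunoSEQ export -> AIRR column mapping, version tag included so the
#: dialect contract is explicit and auditable.
IMMUNOSEQ_COLUMN_MAP_VERSION = "v1"
IMMUNOSEQ_COLUMN_MAP = {
    "nucleotide": "junction",
    "aminoAcid": "junction_aa",
    "vGeneName": "v_call",
    "jGeneName": "j_call",
    "count (templates/reads)": "duplicate_count",
    "sequenceStatus": "productive",
}

_TRUE_STRINGS = {"t", "true", "1", "yes", "y"}
_FALSE_STRINGS = {"f", "false", "0", "no", "n", ""}


def strip_allele(gene_call: str) -> str:
    """Reduce an allele-level call (``TRBV5-1*01``) to its gene (``TRBV5-1``)."""
    return _ALLELE_RE.sub("", gene_call.strip())


class CloneKey(NamedTuple):
    """Cross-sample clone identifier: CDR3 nucleotide + gene-level V/J calls.

    Template counts are rearrangement-level, so the key keeps the nucleotide
    junction; allele suffixes are stripped because allele calls are unstable
    across samples.
    """

    cdr3_nt: str
    v_gene: str
    j_gene: str


@dataclass(frozen=True)
class Clone:
    """One TCR-beta rearrangement with its template count."""

    cdr3_nt: str
    cdr3_aa: str
    v_call: str
    j_call: str
    templates: int
    productive: bool

    def __post_init__(self) -> None:
        if self.templates < 0:
            raise ValueError(f"templates must be >= 0, got {self.templates}")
        if not _CDR3_NT_RE.match(self.cdr3_nt):
            raise ValueError(f"cdr3_nt must be uppercase ACGTN, got {self.cdr3_nt!r}")
        if self.productive:
            if not self.cdr3_aa:
                raise ValueError("productive clone must carry a CDR3 amino-acid sequence")
            # tolerant frame check: aa length cannot exceed what the junction encodes
            if len(self.cdr3_aa) * 3 > len(self.cdr3_nt) + 6:
                raise ValueError(
                    f"cdr3_aa {self.cdr3_aa!r} too long for junction of {len(self.cdr3_nt)} nt"
                )

    @property
    def key(self) -> CloneKey:
        return CloneKey(self.cdr3_nt, strip_allele(self.v_call), strip_allele(self.j_call))


@dataclass
class Repertoire:
    """One sample's clone collection with metadata and template totals."""

    subject_id: str
    timepoint: str
    compartment: str
    clones: dict[CloneKey, Clone] = field(default_factory=dict)

    @property
    def total_templates(self) -> int:
        return sum(c.templates for c in self.clones.values())

    @property
    def total_productive_templates(self) -> int:
        return sum(c.templates for c in self.clones.values() if c.productive)

    def __len__(self) -> int:
        return len(self.clones)

    def add(self, clone: Clone) -> None:
        """Add a clone, aggregating template counts on key collision."""
        key = clone.key
        existing = self.clones.get(key)
        if existing is None:
            self.clones[key] = clone
        else:
            self.clones[key] = replace(existing, templates=existing.templates + clone.templates)

    def productive_counts(self) -> dict[CloneKey, int]:
        """Template counts of productive clones only."""
        return {k: c.templates for k, c in self.clones.items() if c.productive}


def _parse_bool(value, row: int) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE_STRINGS:
        return True
    if s in _FALSE_STRINGS:
        return False
    # ImmunoSEQ sequenceStatus vocabulary
    if s == "in":
        return True
    if s in {"out", "stop"}:
        return False
    raise RowParseError(f"cannot interpret productive flag {value!r} at data row {row}", row=row)


def _parse_count(value, row: int) -> int:
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise RowParseError(f"non-integer template count {value!r} at data row {row}", row=row)
    if not f.is_integer():
        raise RowParseError(f"non-integer template count {value!r} at data row {row}", row=row)
    return int(f)


def read_repertoire(
    path,
    dialect: str = "airr",
    *,
    subject_id: str = "",
    timepoint: str = "",
    compartment: str = "",
) -> Repertoire:
    """Read one repertoire from a TSV file.

    Rows with zero templates are dropped; rows sharing a clone key are
    aggregated by summing templates. Metadata fields are caller-supplied
    (neither dialect embeds them per file).

    Parameters
    ----------
    path
        TSV file with a header row.
    dialect
        ``"airr"`` (AIRR Rearrangement) or ``"immunoseq"`` (export dialect,
        mapped through :data:`IMMUNOSEQ_COLUMN_MAP`).
    """
    if dialect not in ("airr", "immunoseq"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if dialect == "immunoseq":
        known = set(IMMUNOSEQ_COLUMN_MAP)
        extra = [c for c in df.columns if c not in known]
        if extra:
            logger.warning("ignoring %d unmapped ImmunoSEQ columns: %s", len(extra), extra)
        df = df.rename(columns=IMMUNOSEQ_COLUMN_MAP)
    missing = [c for c in AIRR_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing mandatory column(s) {', '.join(missing)} for dialect {dialect!r}"
        )
    rep = Repertoire(subject_id=subject_id, timepoint=timepoint, compartment=compartment)
    for i, row in enumerate(df.itertuples(index=False), start=1):
        templates = _parse_count(getattr(row, "duplicate_count"), i)
        if templates == 0:
            continue
        productive = _parse_bool(getattr(row, "productive"), i)
        clone = Clone(
            cdr3_nt=str(getattr(row, "junction")).strip().upper(),
            cdr3_aa=str(getattr(row, "junction_aa")).strip(),
            v_call=str(getattr(row, "v_call")).strip(),
            j_call=str(getattr(row, "j_call")).strip(),
            templates=templates,
            productive=productive,
        )
        rep.add(clone)
    return rep


def write_repertoire(rep: Repertoire, path, dialect: str = "airr") -> None:
    """Write a repertoire as an AIRR Rearrangement TSV.

    Rows are emitted in sorted clone-key order so output is byte-stable for a
    given repertoire regardless of insertion order.
    """
    if dialect != "airr":
        raise ValueError("only the 'airr' dialect is writable; 'immunoseq' is read-only")
    rows = []
    for key in sorted(rep.clones):
        c = rep.clones[key]
        rows.append(
            {
                "junction": c.cdr3_nt,
                "junction_aa": c.cdr3_aa,
                "v_call": c.v_call,
                "j_call": c.j_call,
                "duplicate_count": c.templates,
                "productive": "T" if c.productive else "F",
            }
        )
    df = pd.DataFrame(rows, columns=list(AIRR_COLUMNS))
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def productive_frequency(rep: Repertoire, key: CloneKey) -> float:
    """A clone's template share among productive templates; 0.0 if absent.

    Frequencies throughout the package are *productive* frequencies: the
    denominator counts templates of in-frame, stop-free rearrangements only.
    """
    total = rep.total_productive_templates
    if total == 0:
        raise UndefinedStatisticError(
            "productive frequency undefined: repertoire has no productive templates"
        )
    clone = rep.clones.get(key)
    if clone is None or not clone.productive:
        return 0.0
    return clone.templates / total
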