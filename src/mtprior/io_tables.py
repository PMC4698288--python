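"""Readers and writers for the tab-delimited tables the workflow consumes.

Dialect: UTF-8, tab-separated, header row mandatory; "." or an empty cell
means missing; decimal point (never comma).  Variant strings are accepted in
the notations tables actually print — "m.3380G>A", "T9185C", "3380A" (ref
not attached), "6691.A" / "m.6691insA" for insertions, "m.3380delG" for
deletions — and normalized to :class:`~mtprior.core.Variant`.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from Bio import SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    AnnotatedVariant,
    CodingEffect,
    MtPosition,
    MtPriorError,
    Variant,
    VariantKind,
)

__all__ = [
    "SchemaError",
    "AlignmentError",
    "VariantTable",
    "MarkerTable",
    "parse_variant",
    "read_variant_table",
    "write_variant_table",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "read_marker_table",
    "write_marker_table",
    "load_fixture",
    "FIXTURE_NAMES",
    "write_prioritization_report",
]


class SchemaError(MtPriorError):
    pass


class AlignmentError(MtPriorError):
    pass


FIXTURE_NAMES = ("table1", "table2", "table3", "table4", "table5")

#: canonical column order for writing variant tables
CANONICAL_COLUMNS = (
    "sample_id",
    "variant",
    "hf",
    "locus",
    "nt_var",
    "aa_change",
    "aa_var",
    "disease_score",
    "coding_effect",
    "recognized_by",
    "haplogroup_defining",
)

_SUB_HGVS = re.compile(r"^m\.(\d+)([ACGT])>([ACGT])$")
_SUB_COMPACT = re.compile(r"^([ACGT])(\d+)([ACGT])$")
_SUB_ALT_ONLY = re.compile(r"^(\d+)([ACGT])$")
_INS_DOT = re.compile(r"^(\d+)\.([ACGT]+)$")
_INS_HGVS = re.compile(r"^m\.(\d+)ins([ACGT]+)$")
_DEL_HGVS = re.compile(r"^m\.(\d+)del([ACGT]*)$")


def parse_variant(text: str) -> Variant:
    """Normalize a printed variant string to a :class:`Variant`."""
    s = text.strip()
    if m := _SUB_HGVS.match(s):
        return Variant(MtPosition(int(m.group(1))), m.group(3), ref=m.group(2))
    if m := _SUB_COMPACT.match(s):
        return Variant(MtPosition(int(m.group(2))), m.group(3), ref=m.group(1))
    if m := _SUB_ALT_ONLY.match(s):
        return Variant(MtPosition(int(m.group(1))), m.group(2))
    if m := (_INS_DOT.match(s) or _INS_HGVS.match(s)):
        return Variant(MtPosition(int(m.group(1))), m.group(2), kind=VariantKind.INSERTION)
    if m := _DEL_HGVS.match(s):
        return Variant(
            MtPosition(int(m.group(1))), m.group(2) or "-", ref=m.group(2) or None,
            kind=VariantKind.DELETION,
        )
    raise SchemaError(f"unrecognized variant notation: {text!r}")


def format_variant(v: Variant) -> str:
    if v.kind is VariantKind.INSERTION:
        return f"{v.pos.pos}.{v.alt}"
    if v.kind is VariantKind.DELETION:
        return f"m.{v.pos.pos}del{v.ref or ''}"
    if v.ref:
        return f"m.{v.pos.pos}{v.ref}>{v.alt}"
    return f"{v.pos.pos}{v.alt}"


@dataclass
class VariantTable:
    """An ordered collection of annotated variants read from one source."""

    rows: list[AnnotatedVariant] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def keys(self) -> list[tuple]:
        return [r.key for r in self.rows]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame([_row_to_record(r) for r in self.rows])


_STOP_RE = re.compile(r"premature\s*stop", re.IGNORECASE)
_AA_RE = re.compile(r"^([A-Z])(\d+)\s?([A-Z*])$")


def effect_from_aa_change(aa_change: str) -> CodingEffect | None:
    """Infer the coding-effect class from a printed amino-acid change."""
    s = aa_change.strip()
    if not s:
        return None
    if _STOP_RE.search(s):
        return CodingEffect.PREMATURE_STOP
    if s.lower() == "frameshift":
        return CodingEffect.FRAMESHIFT
    if m := _AA_RE.match(s):
        ref_aa, _, alt_aa = m.groups()
        if alt_aa == "*":
            return CodingEffect.PREMATURE_STOP
        return CodingEffect.SYNONYMOUS if ref_aa == alt_aa else CodingEffect.NON_SYNONYMOUS
    return None


def _parse_float(cell: str) -> float | None:
    cell = cell.strip()
    if cell in ("", "."):
        return None
    return float(cell)


def _parse_hf(cell: str) -> float | tuple[float, ...] | None:
    cell = cell.strip()
    if cell in ("", "."):
        return None
    if "/" in cell:
        return tuple(float(x) for x in cell.split("/"))
    return float(cell)


def _parse_recognized(cell: str) -> frozenset[str]:
    cell = cell.strip()
    if cell in ("", "."):
        return frozenset()
    return frozenset(t.strip() for t in re.split(r"[,;]", cell) if t.strip())


def _parse_bool(cell: str) -> bool | None:
    cell = cell.strip().lower()
    if cell in ("", "."):
        return None
    return cell in ("1", "true", "yes", "y")


def read_variant_table(path: str | Path, dialect: str = "excel-tab") -> VariantTable:
    """Read a tab-delimited annotated variant table.

    Mandatory columns: ``variant`` (any accepted notation) or the pair
    ``pos`` + ``alt``.  Recognized optional columns are mapped onto
    :class:`AnnotatedVariant` fields; unknown columns are preserved verbatim
    in ``annotations``; empty cells and "." become missing.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, dialect=dialect)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header row required")
        cols = [c.strip() for c in reader.fieldnames]
        if "variant" not in cols and not ("pos" in cols and "alt" in cols):
            missing = {"variant"} if "pos" in cols or "alt" in cols else {"variant (or pos+alt)"}
            raise SchemaError(f"{path}: missing mandatory column(s): {sorted(missing)}")
        rows = []
        for raw in reader:
            rows.append(_record_to_row(raw))
    return VariantTable(rows=rows, provenance=str(path))


_KNOWN = {
    "variant", "pos", "alt", "ref", "sample_id", "locus", "hf", "nt_var",
    "aa_var", "aa_change", "disease_score", "coding_effect", "recognized_by",
    "haplogroup_defining",
}


def _record_to_row(raw: dict[str, str]) -> AnnotatedVariant:
    get = lambda k: (raw.get(k) or "").strip()
    if get("variant"):
        variant = parse_variant(get("variant"))
    else:
        variant = Variant(MtPosition(int(get("pos"))), get("alt"), ref=get("ref") or None)
    effect = None
    if get("coding_effect"):
        effect = CodingEffect(get("coding_effect"))
    elif get("aa_change"):
        effect = effect_from_aa_change(get("aa_change"))
    annotations = {
        k: v.strip() for k, v in raw.items()
        if k and k not in _KNOWN and v is not None and v.strip() not in ("", ".")
    }
    return AnnotatedVariant(
        variant=variant,
        locus=get("locus") or None,
        coding_effect=effect,
        aa_change=get("aa_change"),
        nt_variability=_parse_float(get("nt_var")),
        aa_variability=_parse_float(get("aa_var")),
        disease_score=_parse_float(get("disease_score")),
        hf=_parse_hf(get("hf")),
        recognized_by=_parse_recognized(get("recognized_by")),
        haplogroup_defining=_parse_bool(get("haplogroup_defining")),
        sample_id=get("sample_id"),
        annotations=annotations,
    )


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return format(value, "g")
    return str(value)


def _row_to_record(row: AnnotatedVariant) -> dict[str, str]:
    hf = row.hf
    if isinstance(hf, tuple):
        hf = "/".join(format(h, "g") for h in hf)
    rec = {
        "sample_id": row.sample_id,
        "variant": format_variant(row.variant),
        "hf": _fmt(hf),
        "locus": _fmt(row.locus),
        "nt_var": _fmt(row.nt_variability),
        "aa_change": row.aa_change,
        "aa_var": _fmt(row.aa_variability),
        "disease_score": _fmt(row.disease_score),
        "coding_effect": row.coding_effect.value if row.coding_effect else "",
        "recognized_by": ",".join(sorted(row.recognized_by)),
        "haplogroup_defining": _fmt(row.haplogroup_defining),
    }
    rec.update(row.annotations)
    return rec


def write_variant_table(table: VariantTable, path: str | Path) -> None:
    """Write a variant table in the canonical dialect (read∘write identity)."""
    path = Path(path)
    extra = sorted({k for r in table.rows for k in r.annotations})
    cols = list(CANONICAL_COLUMNS) + extra
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols, dialect="excel-tab")
        writer.writeheader()
        for row in table.rows:
            writer.writerow({c: _row_to_record(row).get(c, "") for c in cols})


# ---------------------------------------------------------------------------
# FASTA multi-alignments

def read_fasta_alignment(
    path: str | Path, haplogroup_delimiter: str = "|"
) -> MultipleSeqAlignment:
    """Read a FASTA multi-alignment; all records must share one width.

    A haplogroup tag is parsed from each header as the token following
    ``haplogroup_delimiter`` and stored in ``record.annotations["haplogroup"]``.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: no FASTA records")
    widths = {len(r.seq) for r in records}
    if len(widths) > 1:
        offending = [f"{r.id} ({len(r.seq)} bp)" for r in records]
        raise AlignmentError(f"{path}: unequal record lengths: {', '.join(offending)}")
    for r in records:
        if haplogroup_delimiter in r.id:
            r.annotations["haplogroup"] = r.id.split(haplogroup_delimiter, 1)[1]
    return MultipleSeqAlignment(records)


def write_fasta_alignment(alignment: MultipleSeqAlignment, path: str | Path) -> None:
    SeqIO.write(list(alignment), str(path), "fasta")


# ---------------------------------------------------------------------------
# Haplogroup marker tables

class UnknownHaplogroupError(MtPriorError):
    pass


@dataclass
class MarkerTable:
    """Haplogroup tree with per-edge marker variants.

    Stored as (haplogroup, parent, markers) triples; ``markers_for`` returns
    the union of markers along the root-to-haplogroup path.
    """

    parents: dict[str, str | None] = field(default_factory=dict)
    markers: dict[str, list[Variant]] = field(default_factory=dict)

    def add(self, haplogroup: str, parent: str | None, markers: list[Variant]) -> None:
        self.parents[haplogroup] = parent
        self.markers[haplogroup] = list(markers)

    def path_to_root(self, haplogroup: str) -> list[str]:
        if haplogroup not in self.parents:
            import difflib

            near = difflib.get_close_matches(haplogroup, self.parents, n=3)
            raise UnknownHaplogroupError(
                f"unknown haplogroup {haplogroup!r}; nearest known: {near or 'none'}"
            )
        path, node, seen = [], haplogroup, set()
        while node is not None:
            if node in seen:
                raise MtPriorError(f"cycle in haplogroup tree at {node!r}")
            seen.add(node)
            path.append(node)
            node = self.parents.get(node)
        return path

    def markers_for(self, haplogroup: str) -> set[tuple]:
        """Marker keys (pos, kind, alt) on the path root -> haplogroup."""
        keys: set[tuple] = set()
        for node in self.path_to_root(haplogroup):
            keys.update(v.key for v in self.markers.get(node, ()))
        return keys

    def __len__(self) -> int:
        return len(self.parents)


def read_marker_table(path: str | Path) -> MarkerTable:
    """Read a three-column TSV: haplogroup, parent (empty for root), markers
    (comma-separated variant strings)."""
    table = MarkerTable()
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, dialect="excel-tab")
        required = {"haplogroup", "parent", "markers"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise SchemaError(f"{path}: marker table needs columns {sorted(required)}")
        for raw in reader:
            hg = raw["haplogroup"].strip()
            parent = raw["parent"].strip() or None
            cell = (raw["markers"] or "").strip()
            markers = [parse_variant(tok) for tok in cell.split(",") if tok.strip()]
            table.add(hg, parent, markers)
    return table


def write_marker_table(table: MarkerTable, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=["haplogroup", "parent", "markers"],
                                dialect="excel-tab")
        writer.writeheader()
        for hg, parent in table.parents.items():
            writer.writerow({
                "haplogroup": hg,
                "parent": parent or "",
                "markers": ",".join(format_variant(v) for v in table.markers.get(hg, [])),
            })


# ---------------------------------------------------------------------------
# Packaged fixtures

def load_fixture(name: str) -> VariantTable:
    """Load one of the packaged variant tables (``table1`` ... ``table5``).

    These are verbatim transcriptions of published prioritization tables:
    the 53-variant training set, the LHON prioritized list, the ovarian
    cancer candidate list, and the COAD tumor-specific and germline lists.
    """
    if name not in FIXTURE_NAMES:
        raise LookupError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    ref = resources.files("mtprior.data").joinpath(f"{name}.tsv")
    with resources.as_file(ref) as p:
        table = read_variant_table(p)
    table.provenance = f"fixture:{name}"
    return table


# ---------------------------------------------------------------------------
# Prioritization reports

def write_prioritization_report(trace, path: str | Path, format: str = "tsv") -> None:
    """Write the full variant list, prioritized rows first, with one pass/fail
    column per cascade step and a final ``prioritized`` flag.

    Output is byte-identical for identical inputs (no timestamps).
    """
    path = Path(path)
    step_names = [name for name, _, _ in trace.steps]
    records = []
    for idx, row in enumerate(trace.table.rows):
        rec = _row_to_record(row)
        for name in step_names:
            outcome = trace.row_outcomes[idx].get(name)
            rec[name] = "" if outcome is None else ("pass" if outcome else "fail")
        rec["prioritized"] = "1" if idx in trace.prioritized_indices else "0"
        records.append((idx, rec))
    # prioritized first, original order preserved within each block
    records.sort(key=lambda t: (t[1]["prioritized"] == "0", t[0]))
    cols = list(CANONICAL_COLUMNS) + sorted(
        {k for _, r in records for k in r if k not in CANONICAL_COLUMNS
         and k not in step_names and k != "prioritized"}
    ) + step_names + ["prioritized"]
    if format == "tsv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=cols, dialect="excel-tab")
            writer.writeheader()
            for _, rec in records:
                writer.writerow({c: rec.get(c, "") for c in cols})
    elif format == "json":
        payload = {
            "steps": [{"name": n, "surviving": c} for n, _, c in trace.steps],
            "rows": [rec for _, rec in records],
        }
        path.write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unknown report format {format!r}")
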