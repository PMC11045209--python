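"""Readers and writers for numbered-sequence files.

Two plain-text dialects are supported:

* **Numbered TSV (long format)** — header
  ``id<TAB>species<TAB>class<TAB>position<TAB>residue``; one occupied position
  per row; positions rendered as the base number immediately followed by an
  optional insertion letter (``100A``).  Lines starting with ``#`` are
  provenance comments and are skipped.

* **Aligned FASTA dialect** — the first record is named ``#POSITIONS`` and its
  "sequence" is a comma-separated list of position labels defining the
  columns; subsequent records use ``-`` for absent positions and carry
  ``species=...;class=...`` key-value pairs on the description line.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import IO, Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .dataset import DOMAIN_CLASSES, VALID_RESIDUES, NumberedSequence, SequenceDataset
from .positions import ChothiaPosition

TSV_HEADER = ("id", "species", "class", "position", "residue")


class ParseError(ValueError):
    """Malformed input, reported with a line number where available."""


def _open(source, mode: str = "r"):
    if isinstance(source, (str, Path)):
        return open(source, mode, encoding="utf-8", newline=""), True
    return source, False


def parse_numbered_table(source: str | Path | IO[str]) -> SequenceDataset:
    """Parse the long-format numbered TSV into a SequenceDataset.

    Duplicate (id, position) pairs, unknown residue letters and positions
    outside 1-113 are hard errors naming the offending line.
    """
    handle, close = _open(source)
    try:
        rows: dict[str, dict] = {}
        header_seen = False
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if not header_seen:
                if tuple(f.strip().lower() for f in fields) != TSV_HEADER:
                    raise ParseError(
                        f"line {lineno}: expected header {'/'.join(TSV_HEADER)}, "
                        f"got {line!r}"
                    )
                header_seen = True
                continue
            if len(fields) != 5:
                raise ParseError(f"line {lineno}: expected 5 tab-separated fields, got {len(fields)}")
            sid, species, cls, pos_label, residue = (f.strip() for f in fields)
            if cls not in DOMAIN_CLASSES:
                raise ParseError(f"line {lineno}: class must be VH or VHH, got {cls!r}")
            try:
                pos = ChothiaPosition.from_label(pos_label)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            if residue not in VALID_RESIDUES:
                raise ParseError(f"line {lineno}: unknown residue letter {residue!r}")
            rec = rows.setdefault(sid, {"species": species, "class": cls, "residues": {}})
            if rec["class"] != cls or rec["species"] != species:
                raise ParseError(f"line {lineno}: inconsistent labels for id {sid!r}")
            if pos in rec["residues"]:
                raise ParseError(f"line {lineno}: duplicate position {pos} for id {sid!r}")
            rec["residues"][pos] = residue
        if not header_seen:
            raise ParseError("empty input: missing header line")
        records = [
            NumberedSequence(sid, rec["species"], rec["class"], rec["residues"])
            for sid, rec in rows.items()
        ]
        return SequenceDataset(records)
    finally:
        if close:
            handle.close()


def write_numbered_table(
    ds: SequenceDataset,
    target: str | Path | IO[str],
    provenance_comments: Iterable[str] = (),
) -> None:
    """Write a dataset as long-format numbered TSV (UTF-8, LF endings)."""
    handle, close = _open(target, "w")
    try:
        for comment in provenance_comments:
            handle.write(f"# {comment}\n")
        handle.write("\t".join(TSV_HEADER) + "\n")
        for rec in ds:
            for pos, res in rec.items():
                handle.write(
                    f"{rec.id}\t{rec.species}\t{rec.domain_class}\t{pos.label}\t{res}\n"
                )
    finally:
        if close:
            handle.close()


def _parse_description_tags(description: str) -> dict[str, str]:
    # description is "<id> key=value;key=value"; values may contain spaces
    _, _, tail = description.partition(" ")
    tags: dict[str, str] = {}
    for token in tail.split(";"):
        if "=" in token:
            key, value = token.split("=", 1)
            tags[key.strip()] = value.strip()
    return tags


def parse_aligned_fasta(source: str | Path | IO[str]) -> SequenceDataset:
    """Parse the aligned FASTA dialect (``#POSITIONS`` column map + ``-`` gaps)."""
    handle, close = _open(source)
    try:
        records = list(SeqIO.parse(handle, "fasta"))
    finally:
        if close:
            handle.close()
    if not records or records[0].id != "#POSITIONS":
        raise ParseError("aligned FASTA must start with a #POSITIONS record")
    labels = [tok.strip() for tok in str(records[0].seq).split(",") if tok.strip()]
    try:
        columns = [ChothiaPosition.from_label(lbl) for lbl in labels]
    except ValueError as exc:
        raise ParseError(f"#POSITIONS record: {exc}") from exc
    out: list[NumberedSequence] = []
    for rec in records[1:]:
        tags = _parse_description_tags(rec.description)
        if "species" not in tags or "class" not in tags:
            raise ParseError(f"record {rec.id!r}: description must carry species=...;class=...")
        seq = str(rec.seq)
        if len(seq) != len(columns):
            raise ParseError(
                f"record {rec.id!r}: {len(seq)} columns, expected {len(columns)}"
            )
        residues: dict[ChothiaPosition, str] = {}
        for pos, res in zip(columns, seq):
            if res == "-":
                continue
            if res not in VALID_RESIDUES:
                raise ParseError(f"record {rec.id!r}: unknown residue letter {res!r}")
            residues[pos] = res
        out.append(NumberedSequence(rec.id, tags["species"], tags["class"], residues))
    return SequenceDataset(out)


def write_aligned_fasta(ds: SequenceDataset, target: str | Path | IO[str]) -> None:
    """Write a dataset in the aligned FASTA dialect.

    Columns are the union of occupied positions across the dataset, in
    Chothia order.
    """
    all_positions = sorted(
        {pos for rec in ds for pos in rec.positions()}, key=lambda p: p.sort_key()
    )
    records = [
        SeqRecord(
            Seq(",".join(p.label for p in all_positions)),
            id="#POSITIONS",
            description="",
        )
    ]
    for rec in ds:
        row = "".join(rec.residue_at(p) or "-" for p in all_positions)
        records.append(
            SeqRecord(
                Seq(row),
                id=rec.id,
                description=f"species={rec.species};class={rec.domain_class}",
            )
        )
    handle, close = _open(target, "w")
    try:
        SeqIO.write(records, handle, "fasta")
    finally:
        if close:
            handle.close()


def dumps_numbered_table(ds: SequenceDataset) -> str:
    buf = _io.StringIO()
    write_numbered_table(ds, buf)
    return buf.getvalue()
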