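"""Readers and writers for the package's plain-text formats.

Canonical dialect: tab-separated values, ``NA`` for missing cells, ``.`` as
the decimal separator, lines starting with ``#`` are comment headers and are
skipped on read.  CSV is accepted on input (extension or sniffed delimiter);
all output is TSV.  Gene sets use the MSigDB GMT convention: one set per
line, ``name<TAB>description<TAB>member1<TAB>member2...``.
"""

from __future__ import annotations

import hashlib
import warnings
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import ValidationError

_MISSING_TOKENS = {"", "NA", "NaN", "nan"}


def _delimiter(path: Path, first_line: str) -> str:
    if path.suffix.lower() == ".csv":
        return ","
    if path.suffix.lower() in {".tsv", ".txt"}:
        return "\t"
    return "\t" if "\t" in first_line else ","


def read_matrix(path) -> pd.DataFrame:
    """Read a feature-by-sample numeric matrix.

    First column holds feature identifiers, the header row holds sample
    identifiers.  Empty cells and ``NA`` are missing.  Duplicate feature or
    sample identifiers, ragged rows and non-numeric cells are errors that
    name the offending identifier or line number.
    """
    path = Path(path)
    lines = [
        (lineno, line.rstrip("\n"))
        for lineno, line in enumerate(path.read_text().splitlines(), start=1)
        if not line.startswith("#") and line.strip() != ""
    ]
    if not lines:
        raise ValidationError(f"{path}: empty matrix file")
    sep = _delimiter(path, lines[0][1])
    header = lines[0][1].split(sep)
    samples = [h.strip() for h in header[1:]]
    if len(samples) != len(set(samples)):
        dups = sorted({s for s in samples if samples.count(s) > 1})
        raise ValidationError(f"{path}: duplicate sample ids: {', '.join(dups)}")
    ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in lines[1:]:
        fields = line.split(sep)
        if len(fields) != len(samples) + 1:
            raise ValidationError(
                f"{path}: line {lineno}: expected {len(samples) + 1} fields, "
                f"got {len(fields)}"
            )
        ids.append(fields[0].strip())
        row = []
        for j, cell in enumerate(fields[1:], start=2):
            cell = cell.strip()
            if cell in _MISSING_TOKENS:
                row.append(np.nan)
                continue
            try:
                row.append(float(cell))
            except ValueError:
                raise ValidationError(
                    f"{path}: line {lineno}: non-numeric cell {cell!r} "
                    f"in field {j}"
                ) from None
        rows.append(row)
    if len(ids) != len(set(ids)):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"{path}: duplicate feature ids: {', '.join(dups)}")
    return pd.DataFrame(rows, index=pd.Index(ids, name="id"), columns=samples)


def write_matrix(frame: pd.DataFrame, path, header_lines: Iterable[str] = ()) -> None:
    """Write a matrix in the canonical TSV dialect (``NA`` missing)."""
    path = Path(path)
    with path.open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("id\t" + "\t".join(str(c) for c in frame.columns) + "\n")
        for idx, row in zip(frame.index, frame.to_numpy()):
            cells = ["NA" if (isinstance(v, float) and np.isnan(v)) else str(v) for v in row]
            fh.write(str(idx) + "\t" + "\t".join(cells) + "\n")


def read_design(path) -> pd.Series:
    """Read a two-column sample→condition design table (TSV, with header)."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if frame.shape[1] < 2:
        raise ValidationError(f"{path}: design table needs two columns (sample, condition)")
    samples = frame.iloc[:, 0].str.strip()
    if samples.duplicated().any():
        dups = sorted(samples[samples.duplicated()].unique())
        raise ValidationError(f"{path}: duplicate sample ids: {', '.join(dups)}")
    return pd.Series(
        frame.iloc[:, 1].str.strip().to_numpy(), index=samples, name="condition"
    )


def write_design(design: pd.Series, path, header_lines: Iterable[str] = ()) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("sample\tcondition\n")
        for sample, condition in design.items():
            fh.write(f"{sample}\t{condition}\n")


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file into an ordered ``{name: members}`` mapping.

    Member symbols are uppercased and whitespace-trimmed.  Duplicate members
    within a set are dropped with a warning; duplicate set names are an
    error; a line with fewer than three fields is an error naming the line.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    lines = path.read_text().splitlines()
    if not any(line.strip() for line in lines):
        raise ValidationError(f"{path}: empty GMT file")
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValidationError(
                f"{path}: line {lineno}: GMT lines need >= 3 tab-separated fields"
            )
        name = fields[0].strip()
        if name in sets:
            raise ValidationError(f"{path}: line {lineno}: duplicate set name {name!r}")
        members: list[str] = []
        seen = set()
        n_dup = 0
        for raw in fields[2:]:
            symbol = raw.strip().upper()
            if not symbol:
                continue
            if symbol in seen:
                n_dup += 1
                continue
            seen.add(symbol)
            members.append(symbol)
        if n_dup:
            warnings.warn(
                f"{path}: set {name!r}: {n_dup} duplicate member(s) dropped",
                stacklevel=2,
            )
        sets[name] = members
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path,
              descriptions: Mapping[str, str] | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def config_hash(obj) -> str:
    """Short stable hash of a configuration mapping, for output headers."""
    canonical = repr(sorted(_flatten(obj))).encode()
    return hashlib.sha256(canonical).hexdigest()[:12]


def _flatten(obj, prefix=""):
    if isinstance(obj, Mapping):
        for key in sorted(obj):
            yield from _flatten(obj[key], f"{prefix}{key}.")
    elif isinstance(obj, (list, tuple)):
        for i, item in enumerate(obj):
            yield from _flatten(item, f"{prefix}{i}.")
    else:
        yield (prefix.rstrip("."), repr(obj))
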