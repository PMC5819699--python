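"""Readers and writers for the external formats the pipeline touches:
FASTA probes, TSV intensity tables, BED peak intervals, RNAplfold-style
``_lunp`` unpaired-probability tables and the model JSON dialect.

Coordinates follow BED conventions (0-based, half-open) throughout.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    pass


@dataclass
class SequenceRecord:
    id: str
    seq: str


@dataclass
class IntensityTable:
    ids: list
    values: np.ndarray
    set_label: str = "none"
    n_dropped: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.ids) != len(self.values):
            raise ParseError("ids and values length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ParseError("duplicate probe ids in intensity table")
        if not np.all(np.isfinite(self.values)):
            raise ParseError("non-finite intensity")
        if self.set_label not in ("A", "B", "none"):
            raise ParseError("set_label must be A, B or none")

    def __len__(self):
        return len(self.ids)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=pd.Index(self.ids, name="probe_id"))


@dataclass
class PeakInterval:
    chrom: str
    start: int
    end: int
    strand: str = "+"
    score: float | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ParseError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in "+-":
            raise ParseError(f"invalid strand {self.strand!r}")


_T_TO_U = str.maketrans("Tt", "Uu")
_RNA_ALPHABET = set("ACGU")


def read_fasta(path) -> list[SequenceRecord]:
    """Read a (possibly multi-line) FASTA file of RNA/DNA sequences.

    T is silently mapped to U; record ids are the header token before the
    first whitespace and must be unique.  Parse errors name the offending
    line number.
    """
    records: list[SequenceRecord] = []
    seen = set()
    cur_id, cur_seq, cur_line = None, [], 0

    def flush():
        if cur_id is None:
            return
        seq = "".join(cur_seq)
        if not seq:
            raise ParseError(f"{path}: empty sequence for record {cur_id!r} (line {cur_line})")
        bad = set(seq) - _RNA_ALPHABET
        if bad:
            raise ParseError(f"{path}: invalid characters {sorted(bad)} in record {cur_id!r}")
        records.append(SequenceRecord(cur_id, seq))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                cur_id = line[1:].split()[0] if len(line) > 1 else ""
                if not cur_id:
                    raise ParseError(f"{path}: empty FASTA header at line {lineno}")
                if cur_id in seen:
                    raise ParseError(f"{path}: duplicate id {cur_id!r} at line {lineno}")
                seen.add(cur_id)
                cur_seq, cur_line = [], lineno
            else:
                if cur_id is None:
                    raise ParseError(f"{path}: sequence before first header at line {lineno}")
                cur_seq.append(line.translate(_T_TO_U).upper())
    flush()
    return records


def write_fasta(path, records) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.seq}\n")


def read_intensities(path, set_label: str = "none", id_col: int = 0,
                     intensity_col: int = -1, header: bool = False) -> IntensityTable:
    """Read an RNAcompete-style TSV of probe intensities.

    The column layout is configurable: by default the first column is the
    probe id and the last is the intensity (an optional middle column may
    carry the probe sequence).  Rows whose intensity is NA/NaN are dropped
    and counted; any other non-numeric intensity is an error.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=0 if header else None, dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("empty intensity file %s", path)
        return IntensityTable([], np.array([]), set_label)
    ids = df.iloc[:, id_col].astype(str)
    raw = df.iloc[:, intensity_col]
    vals = pd.to_numeric(raw, errors="coerce")
    na_like = raw.isna() | raw.astype(str).str.strip().str.upper().isin(
        {"NA", "NAN", ""}
    )
    bad = vals.isna() & ~na_like
    if bad.any():
        i = int(np.argmax(bad.values))
        raise ParseError(f"{path}: non-numeric intensity {raw.iloc[i]!r} for probe {ids.iloc[i]}")
    keep = vals.notna().values
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d NA intensity rows from %s", n_dropped, path)
    return IntensityTable(list(ids[keep]), vals[keep].to_numpy(), set_label, n_dropped)


def write_intensities(path, table: IntensityTable) -> None:
    with open(path, "w") as fh:
        for pid, val in zip(table.ids, table.values):
            fh.write(f"{pid}\t{float(val)!r}\n")


def read_bed(path) -> list[PeakInterval]:
    """Read peak intervals from a BED file (>= 3 columns, 0-based half-open)."""
    peaks = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: fewer than 3 BED columns at line {lineno}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}: non-integer coordinate at line {lineno}") from exc
            score = None
            if len(parts) >= 5 and parts[4] not in (".", ""):
                score = float(parts[4])
            strand = parts[5] if len(parts) >= 6 else "+"
            try:
                peaks.append(PeakInterval(parts[0], start, end, strand, score))
            except ParseError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return peaks


def write_bed(path, peaks) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            score = 0.0 if p.score is None else p.score
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\tpeak{i}\t{score}\t{p.strand}\n")


def read_plfold_unpaired(path) -> np.ndarray:
    """Parse an RNAplfold ``_lunp`` table into a vector of P(unpaired).

    Accepts both the single-column ``-u 1`` dialect and multi-``u`` tables
    (the u=1 column is used).  Lines starting with ``#`` are headers.
    """
    probs = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                pos = int(parts[0])
                val = float(parts[1])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}: malformed _lunp row at line {lineno}") from exc
            if not 0.0 <= val <= 1.0:
                raise ParseError(f"{path}: probability {val} outside [0,1] at line {lineno}")
            probs[pos] = val
    if not probs:
        return np.array([])
    n = max(probs)
    out = np.full(n, np.nan)
    for pos, val in probs.items():
        out[pos - 1] = val
    if np.isnan(out).any():
        raise ParseError(f"{path}: missing positions in _lunp table")
    return out


def write_plfold_unpaired(path, p_unpaired) -> None:
    with open(path, "w") as fh:
        fh.write("#unpaired probabilities\n #i$\tl=1\n")
        for i, v in enumerate(p_unpaired, start=1):
            fh.write(f"{i}\t{float(v)!r}\n")


def paired_from_unpaired(p_unpaired: np.ndarray) -> np.ndarray:
    return 1.0 - np.asarray(p_unpaired, dtype=float)


MODEL_FORMAT_VERSION = 1


def write_model_json(path, model, metadata: dict | None = None) -> None:
    """Serialize a binding model (see :mod:`rbpstruct.model`) to JSON."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "k": int(model.k),
        "seq_weights": np.asarray(model.seq_weights, dtype=float).tolist(),
        "ctx_weights": np.asarray(model.ctx_weights, dtype=float).tolist(),
        "metadata": metadata or getattr(model, "metadata", {}) or {},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_model_json(path):
    from .model import BindingModel

    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ParseError(f"{path}: unsupported model format_version")
    model = BindingModel(
        k=payload["k"],
        seq_weights=np.array(payload["seq_weights"], dtype=float),
        ctx_weights=np.array(payload["ctx_weights"], dtype=float),
        metadata=payload.get("metadata", {}),
    )
    return model
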