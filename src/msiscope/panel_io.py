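"""Marker panel definitions and tabular artifact IO.

The assay interrogates a panel of short (7-12 bp), monomorphic mononucleotide
repeats. Each marker is described by its genomic interval (BED, 0-based
half-open), its repeat unit, its reference ("wild-type", WT) repeat length,
and the two flanking anchor sequences used for alignment-free read anchoring.

This module owns the on-disk dialects shared by the whole pipeline:

* panel        = BED (chrom, start, end, name) + companion TSV with
                 repeat_unit, wt_length, left_flank, right_flank;
* counts table = one row per sample x marker with the consensus-family
                 repeat-length histogram, WT count, total count and WT
                 frequency (tab-delimited, ``#``-prefixed metadata header).

Counts tables are written deterministically (samples sorted, fixed float
formatting) so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .errors import ParseError, ValidationError

__all__ = [
    "MarkerDefinition",
    "MarkerCounts",
    "load_panel",
    "write_panel",
    "panel_hash",
    "write_counts_table",
    "read_counts_table",
    "read_table_metadata",
    "format_histogram",
    "parse_histogram",
]

_DNA = set("ACGT")

#: Marker wt_length must lie in this closed range (panel design constraint:
#: repeats short enough to be monomorphic in the population, long enough to
#: be mutable under mismatch-repair loss).
WT_LENGTH_RANGE = (7, 12)


@dataclass(frozen=True)
class MarkerDefinition:
    """One mononucleotide-repeat marker of the panel.

    Coordinates are 0-based half-open (BED convention); the interval covers
    exactly the reference repeat tract, so ``end - start == wt_length``.
    ``left_flank`` / ``right_flank`` are the anchor sequences immediately
    adjacent to the tract; their tract-facing terminal bases must differ from
    the repeat unit so the anchors unambiguously delimit the homopolymer run.
    """

    marker_id: str
    chrom: str
    start: int
    end: int
    repeat_unit: str
    wt_length: int
    left_flank: str
    right_flank: str

    def __post_init__(self) -> None:
        if not self.marker_id:
            raise ValidationError("marker_id must be non-empty")
        if self.end - self.start != self.wt_length:
            raise ValidationError(
                f"marker {self.marker_id}: BED span {self.end - self.start} "
                f"!= wt_length {self.wt_length}"
            )
        lo, hi = WT_LENGTH_RANGE
        if not lo <= self.wt_length <= hi:
            raise ValidationError(
                f"marker {self.marker_id}: wt_length {self.wt_length} outside [{lo}, {hi}]"
            )
        if self.repeat_unit not in _DNA:
            raise ValidationError(
                f"marker {self.marker_id}: repeat_unit {self.repeat_unit!r} is not a single A/C/G/T"
            )
        for name, flank in (("left_flank", self.left_flank), ("right_flank", self.right_flank)):
            if not flank or set(flank) - _DNA:
                raise ValidationError(
                    f"marker {self.marker_id}: {name} {flank!r} is not uppercase A/C/G/T"
                )
        if self.left_flank[-1] == self.repeat_unit:
            raise ValidationError(
                f"marker {self.marker_id}: left_flank ends in the repeat unit; "
                "anchor would extend the homopolymer run"
            )
        if self.right_flank[0] == self.repeat_unit:
            raise ValidationError(
                f"marker {self.marker_id}: right_flank starts with the repeat unit; "
                "anchor would extend the homopolymer run"
            )


@dataclass(frozen=True)
class MarkerCounts:
    """Consensus-family repeat-length histogram for one marker of one sample.

    ``wt_frequency`` is ``None`` (not 0) when ``total_count == 0``: a marker
    with no coverage carries no frequency information and must be excluded
    from scoring, which the ``qc_pass`` flag makes explicit.
    """

    marker_id: str
    length_histogram: Mapping[int, int]
    wt_count: int
    total_count: int
    wt_frequency: float | None
    qc_pass: bool

    @classmethod
    def from_histogram(
        cls,
        marker_id: str,
        length_histogram: Mapping[int, int],
        wt_length: int,
        min_total: int = 1,
    ) -> "MarkerCounts":
        """Build a consistent record from a raw histogram.

        ``qc_pass`` is true iff ``total_count >= min_total``.
        """
        histogram = {int(k): int(v) for k, v in sorted(length_histogram.items())}
        if any(k < 0 or v < 0 for k, v in histogram.items()):
            raise ValidationError(f"marker {marker_id}: negative length or count in histogram")
        total = sum(histogram.values())
        wt = histogram.get(wt_length, 0)
        freq = wt / total if total > 0 else None
        return cls(
            marker_id=marker_id,
            length_histogram=histogram,
            wt_count=wt,
            total_count=total,
            wt_frequency=freq,
            qc_pass=total >= min_total,
        )

    def validate(self) -> None:
        if self.total_count != sum(self.length_histogram.values()):
            raise ValidationError(
                f"marker {self.marker_id}: total_count {self.total_count} != histogram sum"
            )
        if self.total_count == 0 and self.wt_frequency is not None:
            raise ValidationError(
                f"marker {self.marker_id}: wt_frequency must be undefined at zero coverage"
            )


def _read_lines(path: Path) -> list[str]:
    try:
        return Path(path).read_text().splitlines()
    except OSError as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc


def load_panel(bed_path: str | Path, meta_path: str | Path) -> list[MarkerDefinition]:
    """Load and validate a marker panel from a BED file and its companion TSV.

    The BED supplies (chrom, start, end, marker_id); the TSV, keyed by
    marker_id, supplies repeat_unit, wt_length and the two flank anchors.
    Every :class:`MarkerDefinition` invariant is checked; violations raise
    :class:`ValidationError` naming the marker, malformed lines raise
    :class:`ParseError` naming the file and line number.
    """
    bed_records: list[tuple[str, str, int, int]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(_read_lines(Path(bed_path)), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 4:
            raise ParseError(f"{bed_path}:{lineno}: expected >=4 BED columns, got {len(fields)}")
        chrom, start_s, end_s, name = fields[:4]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ParseError(f"{bed_path}:{lineno}: non-integer coordinates") from exc
        if name in seen:
            raise ValidationError(f"{bed_path}:{lineno}: duplicate marker_id {name!r}")
        seen.add(name)
        bed_records.append((name, chrom, start, end))

    meta: dict[str, dict[str, str]] = {}
    lines = [ln for ln in _read_lines(Path(meta_path)) if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ParseError(f"{meta_path}: empty panel metadata file")
    header = lines[0].split("\t")
    required = {"marker_id", "repeat_unit", "wt_length", "left_flank", "right_flank"}
    missing = required - set(header)
    if missing:
        raise ParseError(f"{meta_path}:1: missing columns {sorted(missing)}")
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ParseError(f"{meta_path}:{lineno}: expected {len(header)} columns, got {len(fields)}")
        row = dict(zip(header, fields))
        meta[row["marker_id"]] = row

    panel = []
    for name, chrom, start, end in bed_records:
        if name not in meta:
            raise ValidationError(f"marker {name}: present in BED but missing from {meta_path}")
        row = meta[name]
        try:
            wt_length = int(row["wt_length"])
        except ValueError as exc:
            raise ParseError(f"{meta_path}: marker {name}: non-integer wt_length") from exc
        panel.append(
            MarkerDefinition(
                marker_id=name,
                chrom=chrom,
                start=start,
                end=end,
                repeat_unit=row["repeat_unit"],
                wt_length=wt_length,
                left_flank=row["left_flank"],
                right_flank=row["right_flank"],
            )
        )
    return panel


def write_panel(panel: Iterable[MarkerDefinition], bed_path: str | Path, meta_path: str | Path) -> None:
    """Write a panel back to the BED + TSV pair read by :func:`load_panel`."""
    panel = list(panel)
    bed_lines = [f"{m.chrom}\t{m.start}\t{m.end}\t{m.marker_id}" for m in panel]
    Path(bed_path).write_text("\n".join(bed_lines) + "\n")
    meta_lines = ["marker_id\trepeat_unit\twt_length\tleft_flank\tright_flank"]
    meta_lines += [
        f"{m.marker_id}\t{m.repeat_unit}\t{m.wt_length}\t{m.left_flank}\t{m.right_flank}"
        for m in panel
    ]
    Path(meta_path).write_text("\n".join(meta_lines) + "\n")


def panel_hash(panel: Iterable[MarkerDefinition]) -> str:
    """Content hash of a panel, used to detect model/counts panel mismatches.

    Marker ids alone cannot distinguish two panels that reuse the same naming
    scheme, so the hash covers every field of every marker.
    """
    payload = json.dumps(
        [
            [m.marker_id, m.chrom, m.start, m.end, m.repeat_unit, m.wt_length, m.left_flank, m.right_flank]
            for m in sorted(panel, key=lambda m: m.marker_id)
        ],
        separators=(",", ":"),
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# counts tables
# ---------------------------------------------------------------------------

_COUNTS_COLUMNS = [
    "sample_id",
    "marker_id",
    "length_histogram",
    "wt_count",
    "total_count",
    "wt_frequency",
    "qc_pass",
]


def format_histogram(histogram: Mapping[int, int]) -> str:
    """Serialize a length histogram as ``length:count`` pairs, lengths ascending."""
    return ",".join(f"{k}:{histogram[k]}" for k in sorted(histogram))


def parse_histogram(text: str) -> dict[int, int]:
    if not text or text == ".":
        return {}
    out: dict[int, int] = {}
    for pair in text.split(","):
        try:
            k, v = pair.split(":")
            out[int(k)] = int(v)
        except ValueError as exc:
            raise ParseError(f"malformed histogram entry {pair!r}") from exc
    return out


def _format_metadata(metadata: Mapping[str, object] | None) -> list[str]:
    if not metadata:
        return []
    return ["# " + json.dumps(dict(metadata), sort_keys=True, separators=(",", ":"))]


def read_table_metadata(path: str | Path) -> dict:
    """Return the JSON metadata header of any msiscope TSV (empty if absent)."""
    meta: dict = {}
    for line in _read_lines(Path(path)):
        if not line.startswith("#"):
            break
        try:
            meta.update(json.loads(line.lstrip("# ")))
        except json.JSONDecodeError:
            continue
    return meta


def write_counts_table(
    samples: Mapping[str, list[MarkerCounts]],
    path: str | Path,
    metadata: Mapping[str, object] | None = None,
) -> None:
    """Write per-sample marker counts to a deterministic TSV.

    Samples are emitted in sorted order; each sample's markers keep the order
    given (normally panel order). Zero-coverage markers must be present,
    flagged ``qc_pass == False``, rather than omitted.
    """
    lines = _format_metadata(metadata)
    lines.append("\t".join(_COUNTS_COLUMNS))
    for sample_id in sorted(samples):
        for mc in samples[sample_id]:
            mc.validate()
            freq = "NA" if mc.wt_frequency is None else repr(mc.wt_frequency)
            lines.append(
                "\t".join(
                    [
                        sample_id,
                        mc.marker_id,
                        format_histogram(mc.length_histogram) or ".",
                        str(mc.wt_count),
                        str(mc.total_count),
                        freq,
                        str(mc.qc_pass),
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_counts_table(path: str | Path) -> dict[str, list[MarkerCounts]]:
    """Read a counts TSV back into the mapping written by :func:`write_counts_table`."""
    lines = [ln for ln in _read_lines(Path(path)) if not ln.startswith("#")]
    if not lines:
        raise ParseError(f"{path}: empty counts table")
    header = lines[0].split("\t")
    missing = set(_COUNTS_COLUMNS) - set(header)
    if missing:
        raise ParseError(f"{path}:1: missing required columns {sorted(missing)}")
    idx = {name: header.index(name) for name in _COUNTS_COLUMNS}
    samples: dict[str, list[MarkerCounts]] = {}
    seen: set[tuple[str, str]] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(header):
            raise ParseError(f"{path}:{lineno}: expected {len(header)} columns, got {len(fields)}")
        sample_id = fields[idx["sample_id"]]
        marker_id = fields[idx["marker_id"]]
        key = (sample_id, marker_id)
        if key in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate row for sample {sample_id}, marker {marker_id}")
        seen.add(key)
        freq_s = fields[idx["wt_frequency"]]
        mc = MarkerCounts(
            marker_id=marker_id,
            length_histogram=parse_histogram(fields[idx["length_histogram"]]),
            wt_count=int(fields[idx["wt_count"]]),
            total_count=int(fields[idx["total_count"]]),
            wt_frequency=None if freq_s == "NA" else float(freq_s),
            qc_pass=fields[idx["qc_pass"]] == "True",
        )
        mc.validate()
        samples.setdefault(sample_id, []).append(mc)
    return samples
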