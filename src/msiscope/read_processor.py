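"""Raw reads -> per-sample marker counts.

The assay measures, at each marker, the fraction of sequenced molecules whose
mononucleotide tract has the reference (WT) length. Rather than aligning
reads to a genome, each read is *anchored*: the marker's two flank sequences
are located in the read (substitutions tolerated, indels not — indels must
stay confined to the homopolymer tract being measured) and the repeat length
is the number of repeat-unit bases strictly between the anchors.

Molecular barcodes (UMIs) attached during single-molecule capture group reads
into families that derive from one original template molecule; a
majority-vote consensus per family suppresses PCR/sequencing slippage, which
is the dominant noise process in short homopolymers.

Pipeline: ``extract_umi`` -> ``anchor_read`` -> ``build_families`` ->
``call_consensus`` -> ``tabulate_sample``. :func:`process_fastq` and
:func:`process_bam` compose the stages and keep read-accounting QC, so every
input read is classified as exactly one of anchored / no-match / umi-no-call.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import InputReadError, ParseError
from .panel_io import MarkerCounts, MarkerDefinition

__all__ = [
    "AnchoredRead",
    "UmiFamily",
    "UmiScheme",
    "AnchorIndex",
    "anchor_read",
    "extract_umi",
    "build_families",
    "call_consensus",
    "tabulate_sample",
    "process_fastq",
    "process_bam",
    "reverse_complement",
    "DEFAULT_MIN_FAMILY_SIZE",
    "DEFAULT_MIN_CONSENSUS_FRACTION",
    "DEFAULT_MIN_MARKER_FAMILIES",
    "DEFAULT_MAX_ANCHOR_MISMATCHES",
]

# Consensus defaults: majority-of->=2 is the minimal family scheme that
# corrects independent per-read slippage; all config-exposed.
DEFAULT_MIN_FAMILY_SIZE = 2
DEFAULT_MIN_CONSENSUS_FRACTION = 0.66
# At assay depths (~3,600 reads/marker) family counts are ample; markers
# with fewer consensus families than this are flagged qc_fail and excluded
# from scoring.
DEFAULT_MIN_MARKER_FAMILIES = 100
DEFAULT_MAX_ANCHOR_MISMATCHES = 1

_VALID_READ_CHARS = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AnchoredRead:
    """A read assigned to one marker with its tract repeat length measured."""

    marker_id: str
    umi: str
    tract_sequence: str
    observed_length: int
    orientation: str  # "forward" | "reverse"


@dataclass
class UmiFamily:
    """All reads sharing one (marker, UMI) key — presumed one template molecule."""

    marker_id: str
    umi: str
    member_lengths: list[int] = field(default_factory=list)
    consensus_length: int | None = None

    @property
    def family_size(self) -> int:
        return len(self.member_lengths)


@dataclass(frozen=True)
class UmiScheme:
    """Where the molecular barcode lives.

    ``read5:<n>`` — the first *n* bases of the read sequence (removed before
    anchoring); ``name:<TAG>`` — a colon-delimited field of the read name,
    the token following ``TAG`` (sequence left untouched).
    """

    kind: str  # "read5" | "name"
    length: int = 5
    tag: str = "UMI"

    @classmethod
    def parse(cls, text: str) -> "UmiScheme":
        kind, _, arg = text.partition(":")
        if kind == "read5":
            try:
                return cls(kind="read5", length=int(arg or "5"))
            except ValueError as exc:
                raise ParseError(f"invalid umi scheme {text!r}") from exc
        if kind == "name":
            return cls(kind="name", tag=arg or "UMI")
        raise ParseError(f"unknown umi scheme {text!r} (expected read5:<n> or name:<tag>)")


def extract_umi(name: str, sequence: str, scheme: UmiScheme) -> tuple[str, str] | None:
    """Return ``(umi, remaining_sequence)``, or ``None`` when no barcode is recoverable.

    A read shorter than an in-read barcode is a no-call (tallied in QC, not an
    error): it cannot carry both a barcode and a usable insert.
    """
    if scheme.kind == "read5":
        if len(sequence) < scheme.length:
            return None
        return sequence[: scheme.length], sequence[scheme.length :]
    tokens = name.split(":")
    for i, token in enumerate(tokens[:-1]):
        if token == scheme.tag:
            return tokens[i + 1], sequence
    return None


class AnchorIndex:
    """Reusable anchoring engine for one panel.

    Assignment rule: the read matches a marker when its left and right flank
    both occur (each with at most ``max_mismatches`` substitutions, left
    before right, no indels inside the anchors). Exactly one matching marker
    is required; zero or several matching markers, or out-of-order anchors,
    yield no-match. The reverse complement is tried when the forward
    orientation fails.

    Resolution order: an exact-match pass over all markers runs first (cheap
    ``str.find``); a unique exact double-anchor hit is accepted without
    consulting the mismatch-tolerant scan, two or more exact hits are
    ambiguous, and only reads with no exact hit enter the vectorized
    Hamming scan over all markers.
    """

    def __init__(self, panel: Sequence[MarkerDefinition], max_mismatches: int = DEFAULT_MAX_ANCHOR_MISMATCHES):
        if not panel:
            raise ValueError("empty panel")
        self.panel = list(panel)
        self.max_mismatches = int(max_mismatches)
        self._flanks = [
            (m, np.frombuffer(m.left_flank.encode(), np.uint8), np.frombuffer(m.right_flank.encode(), np.uint8))
            for m in self.panel
        ]

    # -- matching helpers ---------------------------------------------------

    @staticmethod
    def _exact_hit(seq: str, marker: MarkerDefinition) -> tuple[int, int] | None:
        lpos = seq.find(marker.left_flank)
        if lpos < 0:
            return None
        rpos = seq.find(marker.right_flank, lpos + len(marker.left_flank))
        if rpos < 0:
            return None
        return lpos, rpos

    @staticmethod
    def _hamming_find(arr: np.ndarray, pattern: np.ndarray, k: int, start: int = 0) -> int | None:
        """Leftmost occurrence of ``pattern`` in ``arr[start:]`` with <= k substitutions."""
        n, m = arr.size - start, pattern.size
        if n < m:
            return None
        windows = np.lib.stride_tricks.sliding_window_view(arr[start:], m)
        mismatches = (windows != pattern).sum(axis=1)
        hits = np.flatnonzero(mismatches <= k)
        if hits.size == 0:
            return None
        return start + int(hits[0])

    def _match_oriented(self, seq: str) -> tuple[MarkerDefinition, int, int] | None:
        exact = []
        for m in self.panel:
            hit = self._exact_hit(seq, m)
            if hit is not None:
                exact.append((m, *hit))
                if len(exact) > 1:
                    return None  # ambiguous
        if len(exact) == 1:
            return exact[0]
        if self.max_mismatches == 0:
            return None
        arr = np.frombuffer(seq.encode(), np.uint8)
        fuzzy = []
        for m, larr, rarr in self._flanks:
            lpos = self._hamming_find(arr, larr, self.max_mismatches)
            if lpos is None:
                continue
            rpos = self._hamming_find(arr, rarr, self.max_mismatches, start=lpos + larr.size)
            if rpos is None:
                continue
            fuzzy.append((m, lpos, rpos))
            if len(fuzzy) > 1:
                return None
        return fuzzy[0] if fuzzy else None

    def match(self, sequence: str, umi: str = "") -> AnchoredRead | None:
        bad = set(sequence) - _VALID_READ_CHARS
        if bad:
            raise InputReadError(f"read contains non-DNA characters {sorted(bad)}")
        for orientation, seq in (("forward", sequence), ("reverse", reverse_complement(sequence))):
            hit = self._match_oriented(seq)
            if hit is not None:
                marker, lpos, rpos = hit
                tract = seq[lpos + len(marker.left_flank) : rpos]
                return AnchoredRead(
                    marker_id=marker.marker_id,
                    umi=umi,
                    tract_sequence=tract,
                    observed_length=tract.count(marker.repeat_unit),
                    orientation=orientation,
                )
        return None


def anchor_read(
    read_sequence: str,
    panel: Sequence[MarkerDefinition],
    max_anchor_mismatches: int = DEFAULT_MAX_ANCHOR_MISMATCHES,
    umi: str = "",
) -> AnchoredRead | None:
    """Assign a read to the unique marker whose flanks it contains.

    ``observed_length`` counts repeat-unit bases within the tract (not tract
    width), so an interrupting substitution shortens the call — conservative,
    since interruption and contraction are indistinguishable to a
    frequency-based score. Convenience wrapper; batch callers should reuse an
    :class:`AnchorIndex`.
    """
    return AnchorIndex(panel, max_anchor_mismatches).match(read_sequence, umi=umi)


def build_families(anchored_reads: Iterable[AnchoredRead]) -> list[UmiFamily]:
    """Partition anchored reads into UMI families keyed by (marker_id, umi)."""
    families: dict[tuple[str, str], UmiFamily] = {}
    for read in anchored_reads:
        key = (read.marker_id, read.umi)
        fam = families.get(key)
        if fam is None:
            fam = families[key] = UmiFamily(marker_id=read.marker_id, umi=read.umi)
        fam.member_lengths.append(read.observed_length)
    return list(families.values())


def call_consensus(
    family: UmiFamily,
    min_family_size: int = DEFAULT_MIN_FAMILY_SIZE,
    min_consensus_fraction: float = DEFAULT_MIN_CONSENSUS_FRACTION,
) -> int | None:
    """Majority-vote repeat length of a family, or ``None`` (no-call).

    No-call when the family is undersized, the modal length is tied, or the
    mode's within-family frequency falls below ``min_consensus_fraction``
    (which must exceed 0.5 so the consensus is a true majority).
    """
    if not min_consensus_fraction > 0.5:
        raise ValueError("min_consensus_fraction must exceed 0.5")
    if family.family_size < min_family_size:
        family.consensus_length = None
        return None
    counts = Counter(family.member_lengths)
    (top_length, top_count), *rest = counts.most_common()
    if rest and rest[0][1] == top_count:  # tied mode
        family.consensus_length = None
        return None
    if top_count < min_consensus_fraction * family.family_size:
        family.consensus_length = None
        return None
    family.consensus_length = top_length
    return top_length


def tabulate_sample(
    families: Iterable[UmiFamily],
    panel: Sequence[MarkerDefinition],
    min_marker_families: int = DEFAULT_MIN_MARKER_FAMILIES,
) -> list[MarkerCounts]:
    """Histogram called consensus lengths per marker.

    Every panel marker is present in the output; markers with fewer called
    families than ``min_marker_families`` carry ``qc_pass == False``.
    Families whose consensus was not called contribute nothing.
    """
    per_marker: dict[str, Counter] = {m.marker_id: Counter() for m in panel}
    for fam in families:
        if fam.consensus_length is None:
            continue
        if fam.marker_id in per_marker:
            per_marker[fam.marker_id][fam.consensus_length] += 1
    return [
        MarkerCounts.from_histogram(
            m.marker_id, per_marker[m.marker_id], m.wt_length, min_total=min_marker_families
        )
        for m in panel
    ]


# ---------------------------------------------------------------------------
# file-level drivers
# ---------------------------------------------------------------------------


def _process_records(
    records: Iterable[tuple[str, str]],
    index: AnchorIndex,
    umi_scheme: UmiScheme,
    min_family_size: int,
    min_consensus_fraction: float,
    min_marker_families: int,
) -> tuple[list[MarkerCounts], dict]:
    anchored: list[AnchoredRead] = []
    n_total = n_no_match = n_umi_no_call = 0
    for name, seq in records:
        n_total += 1
        extracted = extract_umi(name, seq.upper(), umi_scheme)
        if extracted is None:
            n_umi_no_call += 1
            continue
        umi, trimmed = extracted
        read = index.match(trimmed, umi=umi)
        if read is None:
            n_no_match += 1
        else:
            anchored.append(read)

    families = build_families(anchored)
    n_consensus_no_call = 0
    size_histogram: Counter = Counter()
    for fam in families:
        size_histogram[fam.family_size] += 1
        if call_consensus(fam, min_family_size, min_consensus_fraction) is None:
            n_consensus_no_call += 1
    counts = tabulate_sample(families, index.panel, min_marker_families)

    qc = {
        "total_reads": n_total,
        "anchored_reads": len(anchored),
        "no_match_reads": n_no_match,
        "umi_no_call_reads": n_umi_no_call,
        "families": len(families),
        "consensus_no_call_families": n_consensus_no_call,
        "family_size_histogram": {str(k): size_histogram[k] for k in sorted(size_histogram)},
    }
    # read-accounting invariant: the three classes partition the input
    assert qc["anchored_reads"] + qc["no_match_reads"] + qc["umi_no_call_reads"] == n_total
    return counts, qc


def process_fastq(
    fastq_paths: str | Path | Sequence[str | Path],
    panel: Sequence[MarkerDefinition],
    umi_scheme: UmiScheme | str = "read5:5",
    max_anchor_mismatches: int = DEFAULT_MAX_ANCHOR_MISMATCHES,
    min_family_size: int = DEFAULT_MIN_FAMILY_SIZE,
    min_consensus_fraction: float = DEFAULT_MIN_CONSENSUS_FRACTION,
    min_marker_families: int = DEFAULT_MIN_MARKER_FAMILIES,
) -> tuple[list[MarkerCounts], dict]:
    """Tabulate one sample from FASTQ (optionally gzipped; R1/R2 given as a list).

    Paired files are processed independently and family-merged through the
    shared (marker, UMI) key. Returns ``(marker_counts, qc_report)``.
    """
    import pysam

    if isinstance(fastq_paths, (str, Path)):
        fastq_paths = [fastq_paths]
    if isinstance(umi_scheme, str):
        umi_scheme = UmiScheme.parse(umi_scheme)
    index = AnchorIndex(panel, max_anchor_mismatches)

    def records():
        for path in fastq_paths:
            with pysam.FastxFile(str(path)) as fh:
                for entry in fh:
                    yield entry.name, entry.sequence

    return _process_records(
        records(), index, umi_scheme, min_family_size, min_consensus_fraction, min_marker_families
    )


def process_bam(
    bam_path: str | Path,
    panel: Sequence[MarkerDefinition],
    umi_scheme: UmiScheme | str = "name:UMI",
    max_anchor_mismatches: int = DEFAULT_MAX_ANCHOR_MISMATCHES,
    min_family_size: int = DEFAULT_MIN_FAMILY_SIZE,
    min_consensus_fraction: float = DEFAULT_MIN_CONSENSUS_FRACTION,
    min_marker_families: int = DEFAULT_MIN_MARKER_FAMILIES,
) -> tuple[list[MarkerCounts], dict]:
    """Tabulate one sample from a coordinate-sorted, indexed BAM.

    The alignment is used only to retrieve candidate reads overlapping each
    marker interval; marker assignment and length measurement are redone with
    the same flank-anchoring procedure as the FASTQ path, because aligner gap
    placement inside homopolymers is unreliable.
    """
    import pysam

    if isinstance(umi_scheme, str):
        umi_scheme = UmiScheme.parse(umi_scheme)
    index = AnchorIndex(panel, max_anchor_mismatches)

    seen: set[str] = set()
    records: list[tuple[str, str]] = []
    with pysam.AlignmentFile(str(bam_path)) as bam:
        for marker in panel:
            for aln in bam.fetch(marker.chrom, marker.start, marker.end):
                if aln.is_secondary or aln.is_supplementary or aln.is_unmapped:
                    continue
                key = aln.query_name + ("/2" if aln.is_read2 else "/1")
                if key in seen or aln.query_sequence is None:
                    continue
                seen.add(key)
                seq = aln.query_sequence
                if aln.is_reverse:
                    # restore original read orientation; anchoring retries RC itself
                    seq = reverse_complement(seq)
                records.append((aln.query_name, seq))

    return _process_records(
        records, index, umi_scheme, min_family_size, min_consensus_fraction, min_marker_families
    )
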