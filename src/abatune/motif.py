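"""Gapped-anchor protein motif scanning.

The conserved abscisic-acid (ABA) binding signature found in plant
phosphodiesterases and related receptor-like proteins is a *gapped* motif:
four constrained residue classes (anchors) separated by variable-length
spacers, written in PROSITE-like syntax::

    [DE].{7,9}[RH].{8,11}[FY].{6,7}[HRK]

A match is any 4-tuple of positions whose residues fall in the anchor
classes and whose inter-anchor spacer lengths lie within the gap bounds.
Scanning enumerates *every* satisfying combination, not just the
leftmost-greedy one, so overlapping alternative placements of the motif
are all reported; protein-level counting collapses them to a boolean.

Coordinates are 1-based inclusive throughout, matching the residue
numbering biochemists use (e.g. "E657", "K685"); converters to 0-based
half-open intervals are provided for interoperating with range tooling.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "STANDARD_AA",
    "AMBIGUOUS_AA",
    "DEFAULT_MOTIF_TEXT",
    "MotifPattern",
    "ProteinRecord",
    "MotifMatch",
    "ScanSummary",
    "parse_motif",
    "scan_sequence",
    "scan_fasta",
    "feature_overlap",
    "read_fasta",
    "read_features",
    "write_matches_tsv",
    "to_zero_based",
    "to_one_based",
]

#: The 20 standard amino-acid letters; only these may appear in anchor classes.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity/non-standard letters tolerated in sequences but never matching
#: an anchor class (conservative: an uncertain residue is not evidence).
AMBIGUOUS_AA = frozenset("BJOUXZ")

#: The ABA-binding signature used throughout this package as the default.
DEFAULT_MOTIF_TEXT = "[DE].{7,9}[RH].{8,11}[FY].{6,7}[HRK]"


class MotifParseError(ValueError):
    """Raised when a gapped-pattern string cannot be parsed."""


@dataclass(frozen=True)
class MotifPattern:
    """A gapped motif: anchor residue classes separated by bounded spacers.

    Parameters
    ----------
    anchors:
        Ordered residue classes; each a frozenset of uppercase one-letter
        amino-acid codes.
    gaps:
        Ordered ``(min, max)`` spacer lengths (residues strictly between
        consecutive anchors). ``len(gaps) == len(anchors) - 1``.
    """

    anchors: tuple[frozenset, ...]
    gaps: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.anchors:
            raise ValueError("pattern needs at least one anchor")
        if len(self.gaps) != len(self.anchors) - 1:
            raise ValueError(
                f"{len(self.anchors)} anchors require {len(self.anchors) - 1} "
                f"gaps, got {len(self.gaps)}"
            )
        for i, a in enumerate(self.anchors):
            if not a:
                raise ValueError(f"anchor {i + 1} is empty")
            bad = set(a) - STANDARD_AA
            if bad:
                raise ValueError(
                    f"anchor {i + 1} contains non-standard letters {sorted(bad)}"
                )
        for i, (lo, hi) in enumerate(self.gaps):
            if not (0 <= lo <= hi):
                raise ValueError(f"gap {i + 1} bounds ({lo},{hi}) violate 0 <= min <= max")

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    def min_span(self) -> int:
        """Shortest sequence length a match can cover (anchors + min gaps)."""
        return self.n_anchors + sum(lo for lo, _ in self.gaps)

    def max_span(self) -> int:
        return self.n_anchors + sum(hi for _, hi in self.gaps)

    def to_text(self) -> str:
        """Canonical pattern text (anchor letters alphabetically sorted)."""
        parts = []
        for i, anchor in enumerate(self.anchors):
            parts.append("[" + "".join(sorted(anchor)) + "]")
            if i < len(self.gaps):
                lo, hi = self.gaps[i]
                parts.append(f".{{{lo},{hi}}}")
        return "".join(parts)


_TOKEN = re.compile(r"\[([A-Za-z]*)\]|\.\{(\d+),(\d+)\}")


def parse_motif(pattern_text: str) -> MotifPattern:
    """Parse PROSITE-like gapped-pattern text into a :class:`MotifPattern`.

    The text must alternate bracketed residue classes ``[XY]`` and spacers
    ``.{min,max}``, starting and ending with a residue class.

    >>> p = parse_motif("[DE].{7,9}[RH].{8,11}[FY].{6,7}[HRK]")
    >>> p.n_anchors, p.gaps[0]
    (4, (7, 9))
    """
    text = pattern_text.strip()
    if not text:
        raise MotifParseError("empty pattern")
    anchors: list[frozenset] = []
    gaps: list[tuple[int, int]] = []
    pos = 0
    expect_anchor = True
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            raise MotifParseError(f"unparseable token at {text[pos:pos + 12]!r}")
        token = m.group(0)
        if m.group(1) is not None:  # anchor class
            if not expect_anchor:
                raise MotifParseError(f"expected a spacer before {token!r}")
            letters = m.group(1).upper()
            if not letters:
                raise MotifParseError(f"empty residue class {token!r}")
            bad = set(letters) - STANDARD_AA
            if bad:
                raise MotifParseError(
                    f"unknown residue letter(s) {sorted(bad)} in {token!r}"
                )
            anchors.append(frozenset(letters))
            expect_anchor = False
        else:  # spacer
            if expect_anchor:
                raise MotifParseError(f"expected a residue class before {token!r}")
            lo, hi = int(m.group(2)), int(m.group(3))
            if lo > hi:
                raise MotifParseError(f"spacer {token!r} has min > max")
            gaps.append((lo, hi))
            expect_anchor = True
        pos = m.end()
    if expect_anchor:
        raise MotifParseError("pattern must end with a residue class, not a spacer")
    return MotifPattern(anchors=tuple(anchors), gaps=tuple(gaps))


@dataclass
class ProteinRecord:
    """One protein sequence with optional feature annotations.

    Features are ``(name, start, end)`` with 1-based inclusive coordinates,
    e.g. a PDE catalytic center annotated as ``("PDE catalytic center", 669, 706)``.
    """

    id: str
    sequence: str
    features: list = field(default_factory=list)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if seq.endswith("*"):
            warnings.warn(
                f"{self.id}: stripping trailing '*' stop character", stacklevel=3
            )
            seq = seq.rstrip("*")
        self.sequence = seq
        for name, start, end in self.features:
            if not (1 <= start <= end <= max(len(seq), 1)):
                raise ValueError(
                    f"{self.id}: feature {name!r} interval ({start},{end}) "
                    f"outside sequence of length {len(seq)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifMatch:
    """One placement of a gapped motif in one protein."""

    protein_id: str
    anchor_positions: tuple[int, ...]  # 1-based, one per anchor
    anchor_residues: str

    @property
    def span(self) -> tuple[int, int]:
        return self.anchor_positions[0], self.anchor_positions[-1]

    def validates_against(self, pattern: MotifPattern) -> bool:
        """Re-check anchor membership and gap bounds for this match."""
        pos = self.anchor_positions
        if len(pos) != pattern.n_anchors or len(self.anchor_residues) != len(pos):
            return False
        if any(b <= a for a, b in zip(pos, pos[1:])):
            return False
        for res, anchor in zip(self.anchor_residues, pattern.anchors):
            if res not in anchor:
                return False
        for (a, b), (lo, hi) in zip(zip(pos, pos[1:]), pattern.gaps):
            if not (lo <= b - a - 1 <= hi):
                return False
        return True


@dataclass
class ScanSummary:
    """Per-protein match lists plus proteome-level counts."""

    matches: dict  # protein_id -> list[MotifMatch]
    n_proteins: int

    @property
    def n_with_match(self) -> int:
        return sum(1 for m in self.matches.values() if m)

    @property
    def fraction_with_match(self) -> float:
        if self.n_proteins == 0:
            return 0.0
        return self.n_with_match / self.n_proteins


def scan_sequence(record: ProteinRecord, pattern: MotifPattern) -> list[MotifMatch]:
    """Enumerate every placement of ``pattern`` in ``record``.

    Returns all distinct anchor-position combinations satisfying every gap
    bound, sorted by span start then lexicographically by anchor positions.
    Ambiguity letters (X, B, Z, J, U, O) never match an anchor class; an
    empty sequence yields an empty list.
    """
    seq = record.sequence
    if not seq:
        return []
    bad = [c for c in set(seq) if c not in STANDARD_AA and c not in AMBIGUOUS_AA]
    if bad:
        raise ValueError(
            f"{record.id}: non-amino-acid characters {sorted(bad)} in sequence"
        )

    # 1-based candidate positions per anchor
    candidates = [
        [i + 1 for i, c in enumerate(seq) if c in anchor] for anchor in pattern.anchors
    ]
    matches: list[MotifMatch] = []

    def extend(level: int, positions: list[int]) -> None:
        if level == pattern.n_anchors:
            pos = tuple(positions)
            matches.append(
                MotifMatch(
                    protein_id=record.id,
                    anchor_positions=pos,
                    anchor_residues="".join(seq[p - 1] for p in pos),
                )
            )
            return
        lo, hi = pattern.gaps[level - 1]
        prev = positions[-1]
        for p in candidates[level]:
            gap = p - prev - 1
            if gap < lo:
                continue
            if gap > hi:
                break  # candidates sorted ascending
            positions.append(p)
            extend(level + 1, positions)
            positions.pop()

    for first in candidates[0]:
        if pattern.n_anchors == 1:
            matches.append(
                MotifMatch(record.id, (first,), seq[first - 1]))
        else:
            extend(1, [first])
    # nested ascending iteration already yields span-start-then-lexicographic order
    return matches


def scan_fasta(
    records: Iterable[ProteinRecord], pattern: MotifPattern
) -> ScanSummary:
    """Scan a collection of proteins; error on duplicate ids."""
    records = list(records)
    if not records:
        raise ValueError("no records to scan")
    seen: dict = {}
    dups = []
    for r in records:
        if r.id in seen:
            dups.append(r.id)
        seen[r.id] = r
    if dups:
        raise ValueError(f"duplicate protein ids: {sorted(set(dups))}")
    return ScanSummary(
        matches={r.id: scan_sequence(r, pattern) for r in records},
        n_proteins=len(records),
    )


def feature_overlap(match: MotifMatch, feature: tuple) -> int:
    """Overlap length (residues) between a match span and a feature interval.

    Both intervals are 1-based inclusive; disjoint intervals return 0.
    The AtKUP5 ABA-binding site (657-685) and PDE catalytic center
    (669-706) overlap by 17 residues.
    """
    _, fstart, fend = feature
    s, e = match.span
    return max(0, min(e, fend) - max(s, fstart) + 1)


# --- coordinate converters (I/O boundary) ---------------------------------

def to_zero_based(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, end


def to_one_based(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


# --- file I/O --------------------------------------------------------------

def read_fasta(path, features: Mapping | None = None) -> list[ProteinRecord]:
    """Read a multi-record FASTA (wrapped or unwrapped) into ProteinRecords."""
    features = features or {}
    return [
        ProteinRecord(id=rec.id, sequence=str(rec.seq), features=list(features.get(rec.id, [])))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_features(path) -> dict:
    """Read a feature table: tab-separated protein_id, name, start, end (1-based)."""
    out: dict = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{ln}: expected >=4 tab-separated columns")
            pid, name, start, end = parts[0], parts[1], int(parts[2]), int(parts[3])
            out.setdefault(pid, []).append((name, start, end))
    return out


def write_matches_tsv(
    summary: ScanSummary,
    path,
    features: Mapping | None = None,
) -> None:
    """Write matches as TSV; annotates the best-overlapping feature if any."""
    features = features or {}
    header = [
        "protein_id", "start", "end", "anchor_positions", "anchor_residues",
        "overlapping_feature", "overlap_len",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for pid in summary.matches:
            for m in summary.matches[pid]:
                best_name, best_len = "", 0
                for feat in features.get(pid, []):
                    ov = feature_overlap(m, feat)
                    if ov > best_len:
                        best_name, best_len = feat[0], ov
                fh.write(
                    "\t".join(
                        [
                            pid,
                            str(m.span[0]),
                            str(m.span[1]),
                            ",".join(map(str, m.anchor_positions)),
                            m.anchor_residues,
                            best_name,
                            str(best_len),
                        ]
                    )
                    + "\n"
                )
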