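"""Per-position conservation scoring of a multiple sequence alignment.

Columns are mapped to reference-sequence numbering by skipping positions
where the reference has a gap.  For each reference position the profile
records residue counts and percentages per configured residue class, e.g.
{F, Y} at cap-loop positions 70/71 or the bulky-side-chain class
{K, I, L, E, V, T, N}.  Percentages are, by default, of all sequences
(gaps counted in the denominator); set ``count_gaps=False`` for percent of
non-gap sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment


@dataclass
class AlignmentProfile:
    """Per-position residue counts (reference numbering) and class percentages."""
    reference_id: str
    n_sequences: int
    counts: dict[int, dict[str, int]]  # position -> residue -> count
    gap_counts: dict[int, int]
    classes: dict[str, frozenset[str]]
    count_gaps: bool = True

    def percent(self, position: int, cls: str) -> float:
        """Percent of sequences whose residue at `position` is in class `cls`."""
        members = self.classes[cls]
        if position not in self.counts:
            raise KeyError(f"position {position} not present in profile "
                           "(reference has a gap there?)")
        col = self.counts[position]
        hits = sum(c for aa, c in col.items() if aa in members)
        denom = self.n_sequences if self.count_gaps \
            else self.n_sequences - self.gap_counts[position]
        return 100.0 * hits / denom if denom else 0.0

    @property
    def positions(self) -> list[int]:
        return sorted(self.counts)


def _load_alignment(alignment) -> MultipleSeqAlignment:
    if isinstance(alignment, MultipleSeqAlignment):
        return alignment
    return AlignIO.read(str(Path(alignment)), "fasta")


def percent_conservation(alignment, reference_id: str,
                         residue_classes: dict[str, str | set[str]] | None = None,
                         count_gaps: bool = True) -> AlignmentProfile:
    """Build a conservation profile mapped to reference-sequence numbering.

    ``alignment`` is an aligned-FASTA path or a Biopython alignment;
    ``residue_classes`` maps class names to residue sets (strings accepted,
    e.g. {"FY": "FY", "bulky": "KILEVTN"}).  Single-letter classes for every
    amino acid observed are always included.
    """
    aln = _load_alignment(alignment)
    ref = None
    for rec in aln:
        if rec.id == reference_id:
            ref = str(rec.seq)
            break
    if ref is None:
        raise KeyError(f"reference sequence {reference_id!r} not in alignment")
    classes: dict[str, frozenset[str]] = {}
    for name, members in (residue_classes or {}).items():
        classes[name] = frozenset(m.upper() for m in members)
    counts: dict[int, dict[str, int]] = {}
    gap_counts: dict[int, int] = {}
    pos = 0
    for col_idx, ref_char in enumerate(ref):
        if ref_char == "-":
            continue  # reference gap: column absent from the profile
        pos += 1
        col: dict[str, int] = {}
        gaps = 0
        for rec in aln:
            aa = str(rec.seq[col_idx]).upper()
            if aa == "-":
                gaps += 1
            else:
                col[aa] = col.get(aa, 0) + 1
        counts[pos] = col
        gap_counts[pos] = gaps
        for aa in col:
            classes.setdefault(aa, frozenset([aa]))
    return AlignmentProfile(reference_id=reference_id, n_sequences=len(aln),
                            counts=counts, gap_counts=gap_counts,
                            classes=classes, count_gaps=count_gaps)


def class_report(profile: AlignmentProfile, positions: list[int],
                 classes: list[str] | None = None) -> pd.DataFrame:
    """Tabulate class percentages at named reference positions.

    Unknown positions are listed with NaN percent and flagged in the
    ``missing`` column rather than raising.
    """
    if classes is None:
        classes = [c for c in profile.classes if len(profile.classes[c]) > 1] \
            or sorted(profile.classes)
    rows = []
    for pos in positions:
        for cls in classes:
            missing = pos not in profile.counts
            rows.append({
                "position": pos,
                "class": cls,
                "percent": float("nan") if missing else profile.percent(pos, cls),
                "missing": missing,
            })
    return pd.DataFrame(rows)
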