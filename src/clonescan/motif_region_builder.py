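"""Construction of control / high / very-high mutation sequence sets.

These 1,500-bp FASTA sets feed external motif-enrichment tools (STREME-style
discriminative discovery): the control set is the central 1.5 kbp
([4250, 5750) window-relative, 0-based half-open) of every 10-kbp tumbling
window carrying no mutation in any clone; the high (very-high) set is every
1-kbp tumbling window where some single clone accumulated more than 5
(more than 10) unique mutations, padded with 250 bp flanks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CONTROL_WINDOW = 10_000
CONTROL_SLICE = (4250, 5750)  # window-relative, 0-based half-open
MUT_WINDOW = 1_000
FLANK = 250
HIGH_THRESHOLD = 5  # strictly more than
VERY_HIGH_THRESHOLD = 10


@dataclass
class SequenceSet:
    label: str  # CONTROL | HIGH | VERY_HIGH
    records: list = field(default_factory=list)  # (chrom, start, end, sequence)

    def __len__(self):
        return len(self.records)

    def write_fasta(self, path) -> None:
        SeqIO.write(
            [
                SeqRecord(Seq(seq), id=f"{chrom}:{start}-{end}:{self.label}", description="")
                for chrom, start, end, seq in self.records
            ],
            str(path),
            "fasta",
        )

    @classmethod
    def read_fasta(cls, path, label) -> "SequenceSet":
        out = cls(label=label)
        for rec in SeqIO.parse(str(path), "fasta"):
            chrom, span, _ = rec.id.split(":")
            start, end = span.split("-")
            out.records.append((chrom, int(start), int(end), str(rec.seq)))
        return out


def _positions_by_chrom(mutations: pd.DataFrame) -> dict:
    """chrom -> sorted 0-based positions (all clones pooled)."""
    out = {}
    for chrom, grp in mutations.groupby("chrom", sort=False):
        out[chrom] = sorted(grp["pos"].to_numpy() - 1)
    return out


def build_control_set(mutations: pd.DataFrame, reference: dict) -> SequenceSet:
    """Central 1.5 kbp of every mutation-free 10-kbp tumbling window.

    ``mutations`` is a chrom/pos table of clone-unique mutations pooled over
    clones (1-based positions). Windows truncated at a chromosome end are
    skipped.
    """
    import numpy as np

    pos_by_chrom = _positions_by_chrom(mutations)
    out = SequenceSet(label="CONTROL")
    lo, hi = CONTROL_SLICE
    for chrom, seq in reference.items():
        positions = np.asarray(pos_by_chrom.get(chrom, []), dtype=int)
        for start in range(0, len(seq) - CONTROL_WINDOW + 1, CONTROL_WINDOW):
            end = start + CONTROL_WINDOW
            n_mut = int(((positions >= start) & (positions < end)).sum()) if positions.size else 0
            if n_mut == 0:
                out.records.append((chrom, start + lo, start + hi, seq[start + lo : start + hi]))
    return out


def build_mutation_sets(
    mutations_by_clone: pd.DataFrame,
    reference: dict,
    thresholds: tuple = (HIGH_THRESHOLD, VERY_HIGH_THRESHOLD),
    stride: int | None = None,
) -> tuple:
    """HIGH and VERY_HIGH 1,500-bp fragment sets from per-clone counts.

    ``mutations_by_clone`` needs chrom, pos (1-based) and clone columns;
    counts are per clone in 1-kbp windows (tumbling by default). A window
    enters HIGH when some clone exceeds thresholds[0] mutations, VERY_HIGH
    when it exceeds thresholds[1] (strict >). Fragments are
    [start - 250, start + 1250); windows whose flanks would cross a
    chromosome edge are skipped. A window qualifying through several clones
    is emitted once.
    """
    import numpy as np

    stride = stride or MUT_WINDOW
    high = SequenceSet(label="HIGH")
    very_high = SequenceSet(label="VERY_HIGH")
    t_high, t_vhigh = thresholds
    for chrom, seq in reference.items():
        sub = mutations_by_clone[mutations_by_clone["chrom"] == chrom]
        if len(sub) == 0:
            continue
        emitted_high, emitted_vhigh = set(), set()
        for clone, grp in sub.groupby("clone", sort=False):
            positions = np.sort(grp["pos"].to_numpy() - 1)
            for start in range(0, len(seq) - MUT_WINDOW + 1, stride):
                end = start + MUT_WINDOW
                count = int(
                    np.searchsorted(positions, end) - np.searchsorted(positions, start)
                )
                if count <= t_high:
                    continue
                frag_lo, frag_hi = start - FLANK, start + MUT_WINDOW + FLANK
                if frag_lo < 0 or frag_hi > len(seq):
                    continue
                if start not in emitted_high:
                    emitted_high.add(start)
                    high.records.append((chrom, frag_lo, frag_hi, seq[frag_lo:frag_hi]))
                if count > t_vhigh and start not in emitted_vhigh:
                    emitted_vhigh.add(start)
                    very_high.records.append((chrom, frag_lo, frag_hi, seq[frag_lo:frag_hi]))
    return high, very_high
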