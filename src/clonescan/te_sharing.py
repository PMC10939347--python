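"""Transposable-element insertion (TEI) sharing analysis.

Non-reference TE insertions are reported per clone as 1-bp "pinpoint"
positions. Pinpoints of the same TE family on the same chromosome that lie
less than 10 kbp apart are treated as one insertion event; with more than
two clones the pairwise rule is applied transitively (single linkage), so a
chained cluster can span more than 10 kbp. Events are never merged across
families or caller methods. The sharing level of an event is the number of
distinct clones among its members.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .summaries import percent

DEFAULT_RADIUS = 10_000  # bp; pinpoints strictly closer than this merge


@dataclass
class TEEvent:
    chrom: str
    family: str
    te_class: str
    method: str
    position: int  # representative (median pinpoint)
    clones: list
    n_insertions: int
    duplicates: int = 0  # same clone seen twice within one cluster

    @property
    def sharing(self) -> int:
        return len(self.clones)


def cluster_tei(insertions: pd.DataFrame, radius: int = DEFAULT_RADIUS) -> list:
    """Single-linkage clustering of pinpoints per (method, chrom, family).

    Consecutive sorted pinpoints strictly closer than ``radius`` link into
    one event. A clone occurring twice in a cluster is counted once and
    flagged in ``duplicates``.
    """
    events = []
    if len(insertions) == 0:
        return events
    for (method, chrom, family), grp in insertions.groupby(
        ["method", "chrom", "family"], sort=True
    ):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        clones = grp["clone"].to_numpy()
        te_class = grp["te_class"].iloc[0]
        breaks = np.flatnonzero(np.diff(pos) >= radius)
        bounds = np.concatenate([[0], breaks + 1, [len(pos)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            members = clones[a:b]
            uniq = sorted(set(members))
            events.append(
                TEEvent(
                    chrom=chrom,
                    family=family,
                    te_class=te_class,
                    method=method,
                    position=int(np.median(pos[a:b])),
                    clones=uniq,
                    n_insertions=int(b - a),
                    duplicates=int(len(members) - len(uniq)),
                )
            )
    return events


def events_frame(events: list) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": e.chrom,
                "position": e.position,
                "family": e.family,
                "te_class": e.te_class,
                "method": e.method,
                "sharing": e.sharing,
                "clones": ",".join(e.clones),
                "n_insertions": e.n_insertions,
                "duplicates": e.duplicates,
            }
            for e in events
        ],
        columns=[
            "chrom",
            "position",
            "family",
            "te_class",
            "method",
            "sharing",
            "clones",
            "n_insertions",
            "duplicates",
        ],
    )


@dataclass
class TESharingSpectrum:
    n_clones: int
    counts: dict  # k -> number of events shared by exactly k clones
    by_class: dict = field(default_factory=dict)  # te_class -> count

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def percent_at(self, k: int) -> float:
        return percent(self.counts.get(k, 0), self.total)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"sharing": k, "events": self.counts.get(k, 0), "percent": self.percent_at(k)}
                for k in range(1, self.n_clones + 1)
            ]
        )


def sharing_spectrum(events: list, n_clones: int) -> TESharingSpectrum:
    counts: dict = {}
    by_class: dict = {}
    for e in events:
        counts[e.sharing] = counts.get(e.sharing, 0) + 1
        by_class[e.te_class] = by_class.get(e.te_class, 0) + 1
    return TESharingSpectrum(n_clones=n_clones, counts=counts, by_class=by_class)


def exclusive_tei_per_clone(events: list) -> dict:
    out: dict = {}
    for e in events:
        if e.sharing == 1:
            out[e.clones[0]] = out.get(e.clones[0], 0) + 1
    return out


def _spearman_rho(x_rank: np.ndarray, y_rank: np.ndarray) -> float:
    return float(np.corrcoef(x_rank, y_rank)[0, 1])


def tei_snp_correlation(
    unique_tei_per_clone: dict,
    unique_snp_per_clone: dict,
    n_mc: int = 100_000,
    seed: int = 0,
) -> dict:
    """Spearman rank correlation between per-clone exclusive TEI and SNPs.

    Ties use mid-ranks. The two-sided p-value enumerates all n! rank
    permutations exactly for n <= 8 clones and falls back to a seeded Monte
    Carlo permutation test for larger panels.
    """
    clones = sorted(set(unique_tei_per_clone) | set(unique_snp_per_clone))
    if len(clones) < 4:
        raise ValueError("need at least 4 clones for a meaningful correlation")
    x = np.array([unique_tei_per_clone.get(c, 0) for c in clones], dtype=float)
    y = np.array([unique_snp_per_clone.get(c, 0) for c in clones], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector; correlation undefined", stacklevel=2)
        return {"rho": math.nan, "p_value": math.nan, "n": len(clones)}
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _spearman_rho(rx, ry)
    n = len(clones)
    sx, sy = rx.std(), ry.std()
    if n <= 8:
        perms = np.array(list(itertools.permutations(range(n))))
        rhos = (ry[perms] @ rx / n - rx.mean() * ry.mean()) / (sx * sy)
        p = float((np.abs(rhos) >= abs(rho) - 1e-12).mean())
    else:
        rng = np.random.default_rng(seed)
        draws = np.array([rng.permutation(n) for _ in range(n_mc)])
        rhos = (ry[draws] @ rx / n - rx.mean() * ry.mean()) / (sx * sy)
        p = (int((np.abs(rhos) >= abs(rho) - 1e-12).sum()) + 1) / (n_mc + 1)
    return {"rho": float(rho), "p_value": float(p), "n": n}


def write_events_bed(events: list, path) -> None:
    with open(path, "w") as fh:
        for e in sorted(events, key=lambda e: (e.chrom, e.position)):
            fh.write(f"{e.chrom}\t{e.position - 1}\t{e.position}\t{e.family};k={e.sharing}\n")
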