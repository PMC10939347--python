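"""Synthetic clone-population generator.

Emulates the data a whole-genome resequencing study of a vegetatively
propagated (clonal) plant panel produces after variant calling: a reference
genome, a multi-sample diploid VCF, per-sample coverage masks, toy gene
models and per-clone transposable-element insertion tables — together with
the ground truth needed to verify every downstream stage.

The genetic model is a star genealogy: a single highly heterozygous ancestor
("varietal" variation against the reference, about 7.3 SNP/kbp and 0.79
INDEL/kbp genome-wide), identical in every clone, plus clone-private somatic
mutations accumulated independently at heterogeneous per-clone rates (one
strongly divergent clone by default). A configurable fraction of the genome
lies in low-variability tracts emulating identity-by-descent with the
reference lineage. An optional unrelated outgroup accession draws its
genotypes independently from the same per-site population allele
frequencies, so that a robust kinship estimator sees ~0.5 between clones and
~0 against the outgroup.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    HET,
    HOMALT,
    HOMREF,
    MISSING,
    CoverageMask,
    GenotypeMatrix,
    intervals_from_bool,
    write_bed,
)
from .effect_annotation import GeneModel, write_gff3
from .vcfio import write_vcf  # noqa: F401  (module surface: simulator owns the writers)

BASES = np.array(list("ACGT"))

DEFAULT_TE_COUNTS = {1: 70, 2: 35, 3: 15, 4: 10, 5: 8, 6: 6, 7: 4, 8: 2}
TE_LIBRARY = [
    # (family, class, sampling weight) — LTR retrotransposons dominate,
    # followed by TIR and MITE DNA transposons.
    ("Gypsy-12", "LTR", 0.30),
    ("Copia-7", "LTR", 0.24),
    ("Mutator-3", "TIR", 0.12),
    ("hAT-9", "TIR", 0.08),
    ("Stowaway-2", "MITE", 0.09),
    ("Tourist-5", "MITE", 0.06),
    ("SINE-1", "SINE", 0.06),
    ("LINE-4", "LINE", 0.05),
]


@dataclass
class SimConfig:
    """Parameters of one synthetic clone panel.

    Rates are genome-wide averages: ``varietal_snp_rate`` (SNP/kbp) and
    ``varietal_indel_rate`` (INDEL/kbp) describe shared ancestral variation
    versus the reference; inside IBD-like tracts (``ibd_fraction`` of the
    genome) the SNP rate drops to ``ibd_rate`` and the non-tract rate is
    raised to preserve the genome-wide average. ``somatic_rates`` are per
    clone in SNP/Mbp (default: first clone 282, the rest uniform in
    [10, 28]).
    """

    seed: int = 0
    n_clones: int = 8
    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000, "chr3": 2_000_000}
    )
    varietal_snp_rate: float = 7.3  # SNP per kbp, genome-wide
    varietal_indel_rate: float = 0.79  # INDEL per kbp
    ibd_fraction: float = 0.10
    # In-tract varietal SNP rate. Chosen so that the TOTAL in-tract density —
    # varietal plus clone-private somatic SNPs (~0.4/kbp at default somatic
    # rates) — stays safely below the 1 SNP/kbp bound that defines a
    # low-variability tract.
    ibd_rate: float = 0.3
    somatic_rates: list | None = None  # per-clone SNP per Mbp
    divergent_rate: float = 282.0
    background_rate_range: tuple = (10.0, 28.0)
    loh_fraction: float = 0.0  # fraction of somatic events that are loss-of-heterozygosity
    missing_rate: float = 0.02  # per-genotype missingness probability
    mean_depth: float = 16.0
    low_qd_fraction: float = 0.02
    qd_value: float = 25.0
    dropout_fraction: float = 0.02  # per-clone coverage-dropout fraction of the genome
    te_counts_by_sharing: dict = field(default_factory=lambda: dict(DEFAULT_TE_COUNTS))
    te_methods: tuple = ("retroseq",)
    te_jitter: int = 2000  # pinpoint jitter, U(-jitter, jitter), < half the merge radius
    outgroup: bool = False
    gene_spacing: int = 50_000

    def __post_init__(self):
        if isinstance(self.chrom_lengths, (list, tuple)):
            self.chrom_lengths = {
                f"chr{i + 1}": int(l) for i, l in enumerate(self.chrom_lengths)
            }
        for r in (self.varietal_snp_rate, self.varietal_indel_rate, self.ibd_rate):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if not 0 <= self.ibd_fraction <= 1:
            raise ValueError("ibd_fraction must be in [0, 1]")
        if sum(self.chrom_lengths.values()) <= 0:
            raise ValueError("total genome length must be positive")
        if self.somatic_rates is not None and any(r < 0 for r in self.somatic_rates):
            raise ValueError("somatic rates must be >= 0")

    @property
    def genome_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    def clone_names(self) -> list:
        return [f"C{i + 1:02d}" for i in range(self.n_clones)]

    def sample_names(self) -> list:
        names = self.clone_names()
        if self.outgroup:
            names.append("OUT")
        return names


@dataclass
class TruthSet:
    """Ground truth written alongside the simulated files."""

    varietal_variants: pd.DataFrame  # chrom, pos, vtype, ancestor genotype
    somatic_variants: dict  # clone -> DataFrame(chrom, pos, vtype, kind)
    te_events: pd.DataFrame  # event_id, chrom, pos, family, te_class, method, sharing, clones
    ibd_tracts: dict  # chrom -> (k, 2) intervals
    somatic_rates: dict  # clone -> SNP/Mbp

    def te_sharing_spectrum(self, method: str) -> dict:
        ev = self.te_events[self.te_events["method"] == method]
        return ev["sharing"].value_counts().to_dict()


@dataclass
class SimResult:
    config: SimConfig
    reference: dict  # chrom -> sequence string
    matrix: GenotypeMatrix
    masks: CoverageMask
    genes: list
    te_insertions: pd.DataFrame  # observed per-clone pinpoint table
    truth: TruthSet


def _random_reference(rng, chrom_lengths) -> dict:
    return {
        c: "".join(BASES[rng.integers(0, 4, size=length)])
        for c, length in chrom_lengths.items()
    }


_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def make_gene_models(rng, chrom_lengths, reference, spacing=50_000) -> list:
    """Plant toy protein-coding genes into the reference.

    Every ``spacing`` bp a gene is laid down with 1-3 CDS segments separated
    by >= 60 bp introns; a valid ORF (ATG ... stop, no internal stops) is
    written into the reference so that planted variants have well-defined
    protein-level consequences. Mutates ``reference`` in place.
    """
    genes = []
    gid = 0
    for chrom, length in chrom_lengths.items():
        seq = np.array(list(reference[chrom]))
        for anchor in range(2_000, length - 5_000, spacing):
            gid += 1
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(1, 4))
            exon_lens = rng.integers(120, 400, size=n_ex)
            total = int(exon_lens.sum())
            total -= total % 3
            exon_lens[-1] -= int(exon_lens.sum()) - total
            cds = "ATG" + "".join(
                rng.choice(_NON_STOP_CODONS, size=total // 3 - 2)
            ) + "TAA"
            if strand == "-":
                genomic = str(Seq(cds).reverse_complement())
            else:
                genomic = cds
            segs, cursor, consumed = [], anchor, 0
            for le in exon_lens:
                le = int(le)
                segs.append((cursor, cursor + le))
                seq[cursor : cursor + le] = list(genomic[consumed : consumed + le])
                consumed += le
                cursor += le + int(rng.integers(60, 200))
            genes.append(
                GeneModel(gene_id=f"gene{gid:04d}", chrom=chrom, strand=strand, cds_segments=segs)
            )
        reference[chrom] = "".join(seq)
    return genes


def _ibd_tracts(rng, chrom_lengths, fraction, grid=50_000) -> dict:
    """Two non-overlapping low-variability tracts per chromosome.

    Tract boundaries snap to a ``grid`` (the analysis window width): real
    IBD tracts are megabase-scale objects that dwarf a 50-kbp window, a
    relation a megabase-long toy chromosome cannot reproduce, so grid
    alignment stands in for "tract >> window" at reduced scale.
    """
    tracts = {}
    for chrom, length in chrom_lengths.items():
        g = min(grid, max(length // 10, 1))
        n_units = max(int(round(fraction * length / g)), 0)
        if n_units == 0:
            tracts[chrom] = np.empty((0, 2), dtype=int)
            continue
        u1 = max(n_units // 2, 1) if n_units > 1 else 1
        u2 = n_units - u1
        slots = length // g
        while True:
            s1 = int(rng.integers(0, max(slots - u1, 1))) * g
            pieces = [(s1, s1 + u1 * g)]
            if u2 > 0:
                s2 = int(rng.integers(0, max(slots - u2, 1))) * g
                pieces.append((s2, s2 + u2 * g))
            pieces.sort()
            if len(pieces) == 1 or pieces[0][1] <= pieces[1][0]:
                tracts[chrom] = np.array(pieces, dtype=int)
                break
    return tracts


def _sample_positions(rng, candidates, n, used) -> np.ndarray:
    """Draw n distinct 0-based positions from candidates, avoiding `used`."""
    n = min(n, len(candidates))
    picked = []
    need = n
    while need > 0:
        draw = rng.choice(candidates, size=min(len(candidates), int(need * 1.3) + 8), replace=False)
        for p in draw:
            p = int(p)
            if p not in used:
                used.add(p)
                picked.append(p)
                if len(picked) == n:
                    break
        need = n - len(picked)
    return np.array(sorted(picked), dtype=int)


def _alt_base(rng, ref_base) -> str:
    choices = [b for b in "ACGT" if b != ref_base]
    return choices[int(rng.integers(0, 3))]


def simulate_population(config: SimConfig) -> SimResult:
    """Generate one synthetic clone panel. Deterministic given the config."""
    rng = np.random.default_rng(config.seed)
    reference = _random_reference(rng, config.chrom_lengths)
    genes = make_gene_models(rng, config.chrom_lengths, reference, config.gene_spacing)
    tracts = _ibd_tracts(rng, config.chrom_lengths, config.ibd_fraction)

    clones = config.clone_names()
    samples = config.sample_names()
    n_samples = len(samples)
    f = config.ibd_fraction
    r_in = config.ibd_rate
    r_out = (
        (config.varietal_snp_rate - f * r_in) / (1 - f)
        if f < 1
        else config.varietal_snp_rate
    )
    if r_out < 0:
        raise ValueError("ibd_rate exceeds the genome-wide varietal rate")

    if config.somatic_rates is not None:
        rates = list(config.somatic_rates)
        if len(rates) != config.n_clones:
            raise ValueError("somatic_rates length must equal n_clones")
    else:
        lo, hi = config.background_rate_range
        rates = [config.divergent_rate] + list(
            rng.uniform(lo, hi, size=config.n_clones - 1)
        )
    somatic_rates = dict(zip(clones, rates))

    site_rows = []  # (chrom, pos1, ref, alt, vtype, origin, clone_or_None)
    gt_rows = []
    used_by_chrom = {c: set() for c in config.chrom_lengths}
    varietal_rows = []
    somatic_rows = {c: [] for c in clones}

    # Base population sites carry an alt-allele frequency a ~ U(lo, hi); the
    # clonal ancestor and the outgroup draw HWE genotypes at it, and a site
    # is kept when it is a variant in at least one sample. The base-site rate
    # is the target varietal rate divided by P(ancestor non-homref) so the
    # realized varietal rate matches the configured genome-wide average.
    AF_LO, AF_HI = 0.05, 0.5
    p_nonref = (AF_LO + AF_HI) - (AF_HI**2 + AF_LO * AF_HI + AF_LO**2) / 3.0

    def hwe_genotype(a):
        u = rng.random()
        if u < (1 - a) ** 2:
            return HOMREF
        if u < (1 - a) ** 2 + 2 * a * (1 - a):
            return HET
        return HOMALT

    for chrom, length in config.chrom_lengths.items():
        tract_mask = np.zeros(length, dtype=bool)
        for a, b in tracts[chrom]:
            tract_mask[a:b] = True
        in_pos_all = np.flatnonzero(tract_mask)
        out_pos_all = np.flatnonzero(~tract_mask)
        used = used_by_chrom[chrom]
        for vtype, rate_out_kbp, rate_in_kbp in (
            ("SNP", r_out, r_in),
            (
                "INDEL",
                config.varietal_indel_rate * (r_out / config.varietal_snp_rate),
                config.varietal_indel_rate * (r_in / config.varietal_snp_rate),
            ),
        ):
            n_out = rng.poisson(rate_out_kbp / p_nonref / 1000.0 * len(out_pos_all))
            n_in = (
                rng.poisson(rate_in_kbp / p_nonref / 1000.0 * len(in_pos_all))
                if len(in_pos_all)
                else 0
            )
            chunks = [_sample_positions(rng, out_pos_all, n_out, used)]
            if n_in:
                chunks.append(_sample_positions(rng, in_pos_all, n_in, used))
            pos0 = np.concatenate(chunks).astype(int)
            for p in pos0:
                p = int(p)
                ref_b = reference[chrom][p]
                a = rng.uniform(AF_LO, AF_HI)
                anc = hwe_genotype(a)
                outg = hwe_genotype(a) if config.outgroup else HOMREF
                if anc == HOMREF and outg == HOMREF:
                    used.discard(p)  # monomorphic in the panel: no record
                    continue
                if vtype == "SNP":
                    ref_a, alt_a = ref_b, _alt_base(rng, ref_b)
                else:
                    ln = min(int(rng.geometric(0.5)), 120)
                    if rng.random() < 0.5 and p + ln + 1 < length:  # deletion
                        ref_a = reference[chrom][p : p + ln + 1]
                        alt_a = ref_b
                    else:  # insertion
                        ref_a = ref_b
                        alt_a = ref_b + "".join(BASES[rng.integers(0, 4, size=ln)])
                row_gt = np.full(n_samples, anc, dtype=np.int8)
                if config.outgroup:
                    row_gt[-1] = outg
                origin = "varietal" if anc != HOMREF else "outgroup_only"
                site_rows.append((chrom, p + 1, ref_a, alt_a, vtype, origin, None))
                gt_rows.append(row_gt)
                if anc != HOMREF:
                    varietal_rows.append((chrom, p + 1, vtype, int(anc)))

    # clone-private somatic SNPs (het gain; optional LOH at varietal sites)
    chrom_names = list(config.chrom_lengths)
    chrom_lens = np.array([config.chrom_lengths[c] for c in chrom_names], dtype=float)
    chrom_weights = chrom_lens / chrom_lens.sum()
    varietal_het_idx = [
        i for i, r in enumerate(site_rows) if r[5] == "varietal" and gt_rows[i][0] == HET
    ]
    loh_used = set()
    for ci, clone in enumerate(clones):
        n_som = rng.poisson(somatic_rates[clone] * config.genome_length / 1e6)
        n_loh = rng.binomial(n_som, config.loh_fraction) if config.loh_fraction > 0 else 0
        n_gain = n_som - n_loh
        per_chrom = rng.multinomial(n_gain, chrom_weights)
        for chrom, k in zip(chrom_names, per_chrom):
            if k == 0:
                continue
            used = used_by_chrom[chrom]
            allpos = np.arange(config.chrom_lengths[chrom])
            for p in _sample_positions(rng, allpos, int(k), used):
                p = int(p)
                ref_b = reference[chrom][p]
                row_gt = np.full(n_samples, HOMREF, dtype=np.int8)
                row_gt[ci] = HET
                site_rows.append((chrom, p + 1, ref_b, _alt_base(rng, ref_b), "SNP", "somatic", clone))
                gt_rows.append(row_gt)
                somatic_rows[clone].append((chrom, p + 1, "SNP", "het_gain"))
        for _ in range(n_loh):
            free = [i for i in varietal_het_idx if i not in loh_used]
            if not free:
                break
            i = free[int(rng.integers(0, len(free)))]
            loh_used.add(i)
            gt_rows[i] = gt_rows[i].copy()
            gt_rows[i][ci] = HOMALT if rng.random() < 0.5 else HOMREF
            somatic_rows[clone].append((site_rows[i][0], site_rows[i][1], site_rows[i][4], "loh"))

    sites = pd.DataFrame(
        [(r[0], r[1], r[2], r[3], r[4]) for r in site_rows],
        columns=["chrom", "pos", "ref", "alt", "vtype"],
    )
    gt = (
        np.vstack(gt_rows)
        if gt_rows
        else np.empty((0, n_samples), dtype=np.int8)
    )
    n_sites = len(sites)

    # site QD and per-genotype depth
    qd = np.full(n_sites, config.qd_value, dtype=float)
    low_qd = rng.random(n_sites) < config.low_qd_fraction
    qd[low_qd] = rng.uniform(2.0, 19.9, size=int(low_qd.sum()))
    sites["qd"] = qd
    dp = rng.poisson(config.mean_depth, size=(n_sites, n_samples)).astype(np.int32)

    # per-sample coverage dropouts
    masks = CoverageMask(chrom_lengths=dict(config.chrom_lengths))
    pos_by_chrom = {c: sites.index[sites["chrom"] == c].to_numpy() for c in chrom_names}
    for si, sample in enumerate(samples):
        intervals = {}
        for chrom, length in config.chrom_lengths.items():
            covered = np.ones(length, dtype=bool)
            total_drop = int(config.dropout_fraction * length)
            n_chunks = 4
            for _ in range(n_chunks):
                le = max(total_drop // n_chunks, 1)
                s = int(rng.integers(0, max(length - le, 1)))
                covered[s : s + le] = False
            intervals[chrom] = intervals_from_bool(covered)
            idx = pos_by_chrom[chrom]
            if len(idx):
                in_drop = ~covered[sites.loc[idx, "pos"].to_numpy() - 1]
                drop_idx = idx[in_drop]
                dp[drop_idx, si] = rng.poisson(1.5, size=len(drop_idx))
        masks.intervals[sample] = intervals

    # genotype missingness
    miss = rng.random((n_sites, n_samples)) < config.missing_rate
    gt = gt.copy()
    gt[miss] = MISSING

    matrix = GenotypeMatrix(samples=samples, sites=sites, gt=gt, dp=dp).sort()

    te_events, te_insertions = _simulate_te(rng, config, somatic_rates)

    truth = TruthSet(
        varietal_variants=pd.DataFrame(
            varietal_rows, columns=["chrom", "pos", "vtype", "ancestor_gt"]
        ),
        somatic_variants={
            c: pd.DataFrame(v, columns=["chrom", "pos", "vtype", "kind"])
            for c, v in somatic_rows.items()
        },
        te_events=te_events,
        ibd_tracts=tracts,
        somatic_rates=somatic_rates,
    )
    return SimResult(
        config=config,
        reference=reference,
        matrix=matrix,
        masks=masks,
        genes=genes,
        te_insertions=te_insertions,
        truth=truth,
    )


def _simulate_te(rng, config: SimConfig, somatic_rates) -> tuple:
    """Plant TE insertion events with a fixed sharing spectrum.

    Events of the same family on the same chromosome are kept >= 25 kbp apart
    so that single-linkage clustering at a 10-kbp radius recovers the planted
    spectrum exactly. Clone-exclusive events are assigned preferentially to
    clones with low somatic SNP rates, mirroring the inverse TEI/SNP
    relationship seen in clonal panels.
    """
    clones = config.clone_names()
    chrom_names = list(config.chrom_lengths)
    chrom_lens = np.array([config.chrom_lengths[c] for c in chrom_names], dtype=float)
    chrom_weights = chrom_lens / chrom_lens.sum()
    fam_weights = np.array([w for _, _, w in TE_LIBRARY])
    fam_weights = fam_weights / fam_weights.sum()
    inv = np.array([1.0 / max(somatic_rates[c], 1e-9) for c in clones])
    excl_weights = inv / inv.sum()

    event_rows, insertion_rows = [], []
    eid = 0
    for method in config.te_methods:
        placed = {}  # (chrom, family) -> list of positions
        for k, count in sorted(config.te_counts_by_sharing.items()):
            k = int(k)
            if k < 1 or k > len(clones):
                raise ValueError(f"sharing level {k} outside 1..{len(clones)}")
            for _ in range(int(count)):
                eid += 1
                # same-family events stay > radius + 2*jitter apart so that
                # single-linkage clustering recovers the spectrum exactly
                min_gap = 10_000 + 2 * config.te_jitter + 500
                for _try in range(2000):
                    fam_i = int(rng.choice(len(TE_LIBRARY), p=fam_weights))
                    family, te_class, _ = TE_LIBRARY[fam_i]
                    chrom = chrom_names[int(rng.choice(len(chrom_names), p=chrom_weights))]
                    pos = int(rng.integers(5000, config.chrom_lengths[chrom] - 5000))
                    near = [
                        q for q in placed.get((chrom, family), []) if abs(q - pos) < min_gap
                    ]
                    if not near:
                        break
                else:
                    raise RuntimeError(
                        "could not place TE event without collision; "
                        "reduce te_counts_by_sharing or enlarge the genome"
                    )
                placed.setdefault((chrom, family), []).append(pos)
                if k == 1:
                    members = [clones[int(rng.choice(len(clones), p=excl_weights))]]
                else:
                    members = list(rng.choice(clones, size=k, replace=False))
                event_rows.append(
                    {
                        "event_id": eid,
                        "chrom": chrom,
                        "pos": pos,
                        "family": family,
                        "te_class": te_class,
                        "method": method,
                        "sharing": k,
                        "clones": ",".join(sorted(members)),
                    }
                )
                for clone in members:
                    jitter = int(rng.integers(-config.te_jitter, config.te_jitter + 1))
                    insertion_rows.append(
                        {
                            "chrom": chrom,
                            "pos": max(1, pos + jitter),
                            "family": family,
                            "te_class": te_class,
                            "clone": clone,
                            "method": method,
                        }
                    )
    te_events = pd.DataFrame(
        event_rows,
        columns=["event_id", "chrom", "pos", "family", "te_class", "method", "sharing", "clones"],
    )
    te_insertions = pd.DataFrame(
        insertion_rows, columns=["chrom", "pos", "family", "te_class", "clone", "method"]
    )
    return te_events, te_insertions


# ---------------------------------------------------------------------------
# writers

def write_fasta(reference: dict, path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in reference.items()],
        str(path),
        "fasta",
    )


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


TE_COLUMNS = ["chrom", "pos", "family", "te_class", "clone", "method"]


def write_te_tables(te_insertions: pd.DataFrame, outdir) -> list:
    """One tab-separated pinpoint table per caller method. Returns paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    methods = list(te_insertions["method"].unique()) if len(te_insertions) else []
    if not methods:
        methods = ["retroseq"]
    for method in methods:
        sub = (
            te_insertions[te_insertions["method"] == method]
            if len(te_insertions)
            else te_insertions
        )
        p = outdir / f"tei_{method}.tsv"
        sub.to_csv(p, sep="\t", index=False, columns=TE_COLUMNS)
        paths.append(p)
    return paths


def read_te_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": int})


def write_masks(masks: CoverageMask, outdir) -> list:
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for sample, by_chrom in masks.intervals.items():
        p = outdir / f"coverage_{sample}.bed"
        write_bed(by_chrom, p)
        paths.append(p)
    return paths


def write_dataset(result: SimResult, outdir) -> dict:
    """Write the full simulated dataset; returns a manifest of paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {}
    write_fasta(result.reference, outdir / "reference.fa")
    manifest["reference"] = str(outdir / "reference.fa")
    write_vcf(result.matrix, outdir / "calls.vcf", result.config.chrom_lengths)
    manifest["vcf"] = str(outdir / "calls.vcf")
    write_gff3(result.genes, outdir / "genes.gff3", result.config.chrom_lengths)
    manifest["gff3"] = str(outdir / "genes.gff3")
    manifest["masks"] = [str(p) for p in write_masks(result.masks, outdir / "masks")]
    manifest["te_tables"] = [str(p) for p in write_te_tables(result.te_insertions, outdir / "te")]
    write_bed(result.truth.ibd_tracts, outdir / "ibd_tracts.bed")
    manifest["ibd_tracts"] = str(outdir / "ibd_tracts.bed")
    return manifest
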