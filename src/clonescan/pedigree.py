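"""Mendelian gene-dropping over small pedigrees at independent loci.

Used as an analytic anchor for the kinship estimator and for
genome-sharing expectations between relatives: founder alleles carry unique
labels, every transmission picks one parental allele uniformly at random,
and identity-by-descent between two individuals is read directly off the
labels. The genome-sharing fraction reported is the standard
(IBD2 + IBD1 / 2), i.e. the expected fraction of alleles shared — 50% for
parent-offspring, 25% for half-siblings, 12.5% for third-degree relatives.
"""

from __future__ import annotations

import numpy as np

from .core import HET, HOMALT, HOMREF


def _founder_alleles(rng, n_founders: int, n_loci: int) -> np.ndarray:
    """Distinct allele labels: founder f carries labels (2f, 2f+1) everywhere."""
    alleles = np.empty((n_founders, n_loci, 2), dtype=np.int64)
    for f in range(n_founders):
        alleles[f, :, 0] = 2 * f
        alleles[f, :, 1] = 2 * f + 1
    return alleles


def _transmit(rng, parent: np.ndarray) -> np.ndarray:
    """One gamete per locus: uniform pick among the parent's two alleles."""
    picks = rng.integers(0, 2, size=parent.shape[0])
    return parent[np.arange(parent.shape[0]), picks]


def drop_half_sibs(n_loci: int, seed: int) -> tuple:
    """Gene-drop two half-siblings (three founders, one shared parent).

    Returns (sib1, sib2) allele-label arrays of shape (n_loci, 2).
    """
    rng = np.random.default_rng(seed)
    founders = _founder_alleles(rng, 3, n_loci)
    shared, other1, other2 = founders
    sib1 = np.stack([_transmit(rng, shared), _transmit(rng, other1)], axis=1)
    sib2 = np.stack([_transmit(rng, shared), _transmit(rng, other2)], axis=1)
    return sib1, sib2


def drop_parent_offspring(n_loci: int, seed: int) -> tuple:
    """Gene-drop a parent and its offspring (other parent unrelated)."""
    rng = np.random.default_rng(seed)
    founders = _founder_alleles(rng, 2, n_loci)
    parent, other = founders
    child = np.stack([_transmit(rng, parent), _transmit(rng, other)], axis=1)
    return parent, child


def ibd_allele_counts(ind1: np.ndarray, ind2: np.ndarray) -> np.ndarray:
    """Per-locus IBD state (0, 1 or 2) between two label arrays.

    Equals the size of the label-set intersection; valid because the
    outbred pedigrees here never produce autozygous (duplicate-label)
    individuals, which is asserted.
    """
    a1, b1 = ind1[:, 0], ind1[:, 1]
    a2, b2 = ind2[:, 0], ind2[:, 1]
    assert (a1 != b1).all() and (a2 != b2).all(), "autozygous individual in outbred pedigree"
    m_a = (a1 == a2) | (a1 == b2)
    m_b = (b1 == a2) | (b1 == b2)
    return m_a.astype(int) + m_b.astype(int)


def shared_genome_fraction(ind1: np.ndarray, ind2: np.ndarray) -> float:
    """Fraction of the genome shared IBD: mean over loci of (IBD state / 2)."""
    return float(ibd_allele_counts(ind1, ind2).mean() / 2.0)


def half_sib_sharing_percent(n_loci: int = 100_000, seed: int = 0) -> float:
    """Expected % genome shared between half-siblings by gene dropping (~25)."""
    sib1, sib2 = drop_half_sibs(n_loci, seed)
    return 100.0 * shared_genome_fraction(sib1, sib2)


def genotypes_from_labels(labels: np.ndarray, alt_carrier: np.ndarray) -> np.ndarray:
    """Collapse allele labels to genotype codes given per-label alt status.

    ``alt_carrier[label, locus]`` is True where that founder allele carries
    the alt base at the locus.
    """
    n_loci = labels.shape[0]
    loci = np.arange(n_loci)
    a = alt_carrier[labels[:, 0], loci].astype(int)
    b = alt_carrier[labels[:, 1], loci].astype(int)
    dosage = a + b
    out = np.full(n_loci, HOMREF, dtype=np.int8)
    out[dosage == 1] = HET
    out[dosage == 2] = HOMALT
    return out


def pedigree_genotypes(n_loci: int, seed: int, relation: str = "parent_offspring") -> tuple:
    """Genotype-code vectors for a related pair at unlinked biallelic loci.

    Founder alleles carry the alt base with probability equal to a per-locus
    allele frequency drawn U(0.05, 0.5), so the pair can feed the KING
    estimator directly.
    """
    rng = np.random.default_rng(seed + 1)
    if relation == "parent_offspring":
        ind1, ind2 = drop_parent_offspring(n_loci, seed)
        n_founders = 2
    elif relation == "half_sibs":
        ind1, ind2 = drop_half_sibs(n_loci, seed)
        n_founders = 3
    else:
        raise ValueError(f"unknown relation {relation!r}")
    freqs = rng.uniform(0.05, 0.5, size=n_loci)
    alt_carrier = rng.random((2 * n_founders, n_loci)) < freqs[None, :]
    return genotypes_from_labels(ind1, alt_carrier), genotypes_from_labels(ind2, alt_carrier)
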