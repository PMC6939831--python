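"""Candidate-locus characterization.

Variant coding-effect classification against a gene annotation and
reference sequence, per-SNP Fisher exact allele-frequency tests between
the two groups, and term enrichment of candidate gene sets (chi-square
with a Fisher fallback when expected counts are small).
"""

from __future__ import annotations

import enum
import functools
import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from Bio.Seq import Seq

from .core import MISSING, FRESHWATER, MIGRATORY, Gene, GeneAnnotation, GenotypeDataset, SampleGrouping, ValidationError

log = logging.getLogger(__name__)


class EffectClass(enum.Enum):
    CODING_SYNONYMOUS = "coding_synonymous"
    CODING_NONSYNONYMOUS = "coding_nonsynonymous"
    INTRONIC = "intronic"
    UPSTREAM = "upstream"
    DOWNSTREAM = "downstream"
    INTERGENIC = "intergenic"


# severity used when a variant hits features of several genes
_SEVERITY = {
    EffectClass.CODING_NONSYNONYMOUS: 0,
    EffectClass.CODING_SYNONYMOUS: 0,
    EffectClass.INTRONIC: 1,
    EffectClass.UPSTREAM: 2,
    EffectClass.DOWNSTREAM: 2,
    EffectClass.INTERGENIC: 3,
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def classify_effect(variant: tuple[str, int, str, str], ann: GeneAnnotation,
                    ref_seqs: dict[str, str], flank: int = 5000) -> EffectClass | None:
    """Classify one SNP by its position relative to the annotation.

    ``variant`` is ``(chrom, pos, ref, alt)`` with a 1-based position.
    In a CDS the containing codon is translated with the ref and the alt
    base (reverse-complemented on the minus strand, codon phase from the
    cumulative CDS length in transcription order): equal amino acids mean
    synonymous.  Inside a gene but outside its CDS is intronic; within
    ``flank`` bp 5' of a gene (strand-aware) is upstream, within ``flank``
    bp 3' downstream; anything else intergenic.  When several genes
    apply, the most severe class wins (coding > intronic > up/downstream
    > intergenic), ties broken by the nearest gene.  Returns None when an
    ambiguity base (N) lands in the codon; genes whose CDS length is not
    a multiple of 3 are excluded with a warning.
    """
    chrom, pos, ref, alt = variant
    if chrom not in ref_seqs:
        raise ValidationError(f"variant chrom {chrom!r} absent from reference")
    seq = ref_seqs[chrom]
    if not (1 <= pos <= len(seq)):
        raise ValidationError(f"variant position {chrom}:{pos} outside reference")
    if seq[pos - 1] != ref:
        raise ValidationError(
            f"reference mismatch at {chrom}:{pos}: FASTA has {seq[pos - 1]!r}, "
            f"variant ref is {ref!r}")

    calls: list[tuple[int, int, EffectClass]] = []   # (severity, distance, class)
    for gene in ann.genes:
        if gene.chrom != chrom:
            continue
        call = _classify_against_gene(pos, ref, alt, gene, seq, flank)
        if call is None:
            continue
        cls, dist = call
        if cls is None:      # N in codon: variant excluded
            return None
        calls.append((_SEVERITY[cls], dist, cls))
    if not calls:
        return EffectClass.INTERGENIC
    calls.sort(key=lambda t: (t[0], t[1]))
    return calls[0][2]


def _classify_against_gene(pos: int, ref: str, alt: str, gene: Gene,
                           seq: str, flank: int):
    """(EffectClass|None, distance) for one gene, or None if out of range."""
    if gene.start <= pos <= gene.end:
        for s, e in gene.cds:
            if s <= pos <= e:
                return _codon_call(pos, ref, alt, gene, seq), 0
        return EffectClass.INTRONIC, 0
    dist = gene.start - pos if pos < gene.start else pos - gene.end
    if dist > flank:
        return None
    before = pos < gene.start
    if gene.strand == "+":
        cls = EffectClass.UPSTREAM if before else EffectClass.DOWNSTREAM
    else:
        cls = EffectClass.DOWNSTREAM if before else EffectClass.UPSTREAM
    return cls, dist


def _codon_call(pos: int, ref: str, alt: str, gene: Gene, seq: str):
    if gene.cds_length % 3 != 0:
        log.warning("gene %s: CDS length %d not a multiple of 3; excluded",
                    gene.gene_id, gene.cds_length)
        return None
    # CDS coordinate of the variant in transcription (5'->3') order
    offset = 0
    cds_index = None
    for s, e in gene.cds:
        if s <= pos <= e:
            cds_index = offset + (pos - s if gene.strand == "+" else e - pos)
            break
        offset += e - s + 1
    assert cds_index is not None
    cds_seq = _cds_sequence(gene, seq)
    codon_idx, phase = divmod(cds_index, 3)
    codon = cds_seq[3 * codon_idx: 3 * codon_idx + 3]
    alt_base = alt if gene.strand == "+" else alt.translate(_COMPLEMENT)
    alt_codon = codon[:phase] + alt_base + codon[phase + 1:]
    if "N" in codon or "N" in alt_codon:
        log.warning("gene %s: ambiguity base in codon at pos %d; variant excluded",
                    gene.gene_id, pos)
        return None
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    return (EffectClass.CODING_SYNONYMOUS if aa_ref == aa_alt
            else EffectClass.CODING_NONSYNONYMOUS)


def _cds_sequence(gene: Gene, seq: str) -> str:
    parts = []
    for s, e in gene.cds:
        sub = seq[s - 1:e]
        if gene.strand == "-":
            sub = sub.translate(_COMPLEMENT)[::-1]
        parts.append(sub)
    return "".join(parts)


def classify_effects(ds: GenotypeDataset, ann: GeneAnnotation,
                     ref_seqs: dict[str, str], flank: int = 5000) -> pd.DataFrame:
    """Effect class for every site of a dataset (one row per site)."""
    rows = []
    for site in ds.sites.itertuples(index=False):
        cls = classify_effect((site.chrom, int(site.pos), site.ref, site.alt),
                              ann, ref_seqs, flank=flank)
        rows.append({"chrom": site.chrom, "pos": int(site.pos),
                     "ref": site.ref, "alt": site.alt,
                     "effect": cls.value if cls is not None else "excluded"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fisher exact test

def fisher_exact(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Point-probability ordering: the p-value sums the hypergeometric
    probabilities of every table with the observed margins whose point
    probability is at most the observed one (1e-12 relative slack for
    floating-point ties).  A table with a zero margin has p = 1 by
    convention.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("need a 2x2 table of non-negative counts")
    r1, r2 = int(t[0].sum()), int(t[1].sum())
    c1 = int(t[0, 0] + t[1, 0])
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        log.debug("fisher_exact: zero margin, p = 1 by convention")
        return 1.0
    a = int(t[0, 0])
    lo = max(0, c1 - r2)
    pmf = _hypergeom_pmf(n, r1, c1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


@functools.lru_cache(maxsize=None)
def _hypergeom_pmf(n: int, r1: int, c1: int) -> np.ndarray:
    """Hypergeometric pmf over the support of a (r1, n-r1) x (c1, n-c1)
    margin family.  Cached: association scans and exhaustive checks hit
    the same margins repeatedly."""
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    support = np.arange(lo, hi + 1)
    return stats.hypergeom.pmf(support, n, r1, c1)


def allele_assoc_scan(ds: GenotypeDataset, grouping: SampleGrouping,
                      sites: np.ndarray | None = None,
                      alpha: float = 0.01) -> pd.DataFrame:
    """Per-site Fisher exact allele-frequency test between the groups.

    Builds, per site, the 2x2 table of (group x {ref, alt}) allele counts
    from non-missing dosages.  Reports raw p, Benjamini-Hochberg q, and a
    flag for raw p < ``alpha``.  Overall-monomorphic sites get p = 1.
    """
    grouping.validate_against(ds)
    if sites is None:
        sites = np.arange(ds.n_sites)
    sites = np.asarray(sites, dtype=int)
    idx1 = ds.sample_index(grouping.members(MIGRATORY))
    idx2 = ds.sample_index(grouping.members(FRESHWATER))
    rows = []
    for j in sites:
        site = ds.sites.iloc[j]
        cells = []
        for idx in (idx1, idx2):
            g = ds.dosages[idx, j]
            obs = g != MISSING
            alt = int(g[obs].sum())
            total = 2 * int(obs.sum())
            cells.append((total - alt, alt))
        table = np.array(cells)
        mono = table[:, 1].sum() == 0 or table[:, 0].sum() == 0
        p = 1.0 if mono else fisher_exact(table)
        rows.append({"chrom": site["chrom"], "pos": int(site["pos"]),
                     "ref": site["ref"], "alt": site["alt"],
                     "ref_mig": int(table[0, 0]), "alt_mig": int(table[0, 1]),
                     "ref_fw": int(table[1, 0]), "alt_fw": int(table[1, 1]),
                     "monomorphic": bool(mono), "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["p"] < alpha
    else:
        df["q"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df


# ---------------------------------------------------------------------------
# Term enrichment

def enrich_terms(candidates: set[str], background: set[str],
                 term_map: dict[str, list[str]],
                 alpha: float = 0.05) -> pd.DataFrame:
    """Term over-representation in a candidate gene set.

    For each term a 2x2 table (candidate vs rest x has-term vs not) is
    tested with a 1-df chi-square without continuity correction when all
    expected counts are >= 5, and with the Fisher exact test otherwise.
    Genes in ``term_map`` that are not in the background are skipped with
    a warning.  Output is sorted by raw p; Benjamini-Hochberg q values
    are reported alongside.
    """
    candidates = set(candidates)
    background = set(background)
    if not candidates <= background:
        raise ValidationError("candidate genes must be a subset of the background")
    stray = set(term_map) - background
    if stray:
        log.warning("enrich_terms: %d mapped genes absent from background, skipped",
                    len(stray))
    term_genes: dict[str, set[str]] = {}
    for gene, terms in term_map.items():
        if gene not in background:
            continue
        for term in terms:
            term_genes.setdefault(term, set()).add(gene)

    n_bg = len(background)
    n_cand = len(candidates)
    rows = []
    for term, genes in sorted(term_genes.items()):
        k = len(genes & candidates)                # candidates with term
        big_k = len(genes)                         # background with term
        table = np.array([[k, n_cand - k],
                          [big_k - k, (n_bg - n_cand) - (big_k - k)]])
        expected = (table.sum(axis=1)[:, None] * table.sum(axis=0)[None, :]
                    / table.sum())
        if (expected >= 5).all():
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
            branch = "chi2"
        else:
            p = fisher_exact(table)
            branch = "fisher"
        rows.append({"term": term, "k": k, "K": big_k, "n": n_cand,
                     "N": n_bg, "branch": branch, "p": float(p)})
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "branch", "p"])
    if len(df):
        df["q"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["p"] < alpha
        df = df.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        df["q"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df
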