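"""Synthetic data with the statistical structure the analysis assumes.

Two populations diverge by drift under the Balding-Nichols model: each
site has an ancestral allele frequency p drawn uniformly on (0.05, 0.95),
and each population's frequency is Beta-distributed around p with
dispersion set by that population's F.  Inside planted sweep intervals
the freshwater population experiences much stronger drift (high F) and
its minor-allele frequency is additionally shrunk toward fixation, which
reproduces the sweep signature the scan is built to detect: reduced
freshwater diversity and elevated divergence.  No linkage disequilibrium
or hitchhiking dynamics are simulated — sweeps are planted as marginal
frequency distortions.

All draws come from one seeded NumPy generator in a fixed documented
order, so a fixed config is byte-reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import MISSING, FRESHWATER, MIGRATORY, Gene, GeneAnnotation, GenotypeDataset, SampleGrouping

_BASES = np.array(list("ACGT"))

#: Default chromosome layout: two 500-kb chromosomes, one 25-kb sweep each.
DEFAULT_CHROM_LENGTHS = {"chr1": 500_000, "chr2": 500_000}
DEFAULT_SWEEPS = [("chr1", 250_001, 275_000), ("chr2", 250_001, 275_000)]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic two-population cohort.

    Defaults mirror the real study design: 85 migratory and 11 freshwater
    resident individuals, weak genome-wide background divergence and
    strong localized drift plus diversity loss inside sweep intervals.
    """

    n_migratory: int = 85
    n_freshwater: int = 11
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS))
    snp_density: float = 1.0 / 200.0
    background_fst_drift: float = 0.02
    sweep_intervals: list[tuple[str, int, int]] = field(
        default_factory=lambda: list(DEFAULT_SWEEPS))
    sweep_drift_freshwater: float = 0.6
    sweep_diversity_scale: float = 0.1
    missing_rate: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("snp_density", "background_fst_drift",
                     "sweep_drift_freshwater", "sweep_diversity_scale",
                     "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_migratory < 2 or self.n_freshwater < 2:
            raise ValueError("each group needs at least 2 samples")
        for chrom, start, end in self.sweep_intervals:
            if chrom not in self.chrom_lengths:
                raise ValueError(f"sweep interval on unknown chrom {chrom!r}")
            if not (1 <= start <= end <= self.chrom_lengths[chrom]):
                raise ValueError(f"sweep interval ({start},{end}) outside {chrom}")


@dataclass
class TruthRecord:
    """What was planted: sweep intervals and per-site frequencies."""

    sweep_intervals: list[tuple[str, int, int]]
    site_frequencies: pd.DataFrame  # chrom, pos, p_ancestral, p_mig, p_fw, in_sweep
    seed: int


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """Population frequencies under the Balding-Nichols Beta model."""
    if f <= 0:
        return p.copy()
    a = p * (1.0 - f) / f
    b = (1.0 - p) * (1.0 - f) / f
    return rng.beta(a, b)


def simulate_dataset(cfg: SimulationConfig) -> tuple[GenotypeDataset, TruthRecord]:
    """Draw a two-population genotype matrix with planted sweeps.

    Draw order (fixed for reproducibility): per chromosome positions and
    alleles, then ancestral frequencies, per-population Balding-Nichols
    frequencies, sweep distortion, genotypes (two Bernoulli allele draws
    per individual as a Binomial(2, p)), and finally missingness.
    """
    rng = np.random.default_rng(cfg.seed)
    chroms, poss, refs, alts = [], [], [], []
    for chrom in cfg.chrom_lengths:  # insertion order: deterministic
        length = cfg.chrom_lengths[chrom]
        n_exp = int(round(length * cfg.snp_density))
        pos = np.unique(rng.integers(1, length + 1, size=n_exp))
        ref_idx = rng.integers(0, 4, size=pos.size)
        alt_idx = (ref_idx + rng.integers(1, 4, size=pos.size)) % 4
        chroms.extend([chrom] * pos.size)
        poss.extend(pos.tolist())
        refs.extend(_BASES[ref_idx].tolist())
        alts.extend(_BASES[alt_idx].tolist())
    n_sites = len(poss)
    if n_sites == 0:
        raise ValueError("no sites left after position deduplication")
    sites = pd.DataFrame({"chrom": chroms, "pos": poss, "ref": refs, "alt": alts})

    in_sweep = np.zeros(n_sites, dtype=bool)
    for chrom, start, end in cfg.sweep_intervals:
        in_sweep |= ((sites["chrom"] == chrom)
                     & (sites["pos"] >= start) & (sites["pos"] <= end)).to_numpy()

    p_anc = rng.uniform(0.05, 0.95, size=n_sites)
    p_mig = _balding_nichols(rng, p_anc, cfg.background_fst_drift)
    p_fw = _balding_nichols(rng, p_anc, cfg.background_fst_drift)
    p_fw_sweep = _balding_nichols(rng, p_anc, cfg.sweep_drift_freshwater)
    p_fw = np.where(in_sweep, p_fw_sweep, p_fw)
    # push the freshwater minor allele toward loss inside sweeps
    minor_is_alt = p_fw <= 0.5
    shrunk = np.where(minor_is_alt,
                      p_fw * cfg.sweep_diversity_scale,
                      1.0 - (1.0 - p_fw) * cfg.sweep_diversity_scale)
    p_fw = np.where(in_sweep, shrunk, p_fw)

    n_total = cfg.n_migratory + cfg.n_freshwater
    dosages = np.empty((n_total, n_sites), dtype=np.int8)
    dosages[:cfg.n_migratory] = rng.binomial(
        2, p_mig, size=(cfg.n_migratory, n_sites))
    dosages[cfg.n_migratory:] = rng.binomial(
        2, p_fw, size=(cfg.n_freshwater, n_sites))
    miss = rng.random(size=dosages.shape) < cfg.missing_rate
    dosages[miss] = MISSING

    sample_ids = ([f"mig{i:03d}" for i in range(cfg.n_migratory)]
                  + [f"fw{i:03d}" for i in range(cfg.n_freshwater)])
    ds = GenotypeDataset(sample_ids=sample_ids, sites=sites, dosages=dosages)
    truth = TruthRecord(
        sweep_intervals=list(cfg.sweep_intervals),
        site_frequencies=pd.DataFrame({
            "chrom": sites["chrom"], "pos": sites["pos"],
            "p_ancestral": p_anc, "p_mig": p_mig, "p_fw": p_fw,
            "in_sweep": in_sweep}),
        seed=cfg.seed)
    return ds, truth


def true_grouping(cfg: SimulationConfig) -> SampleGrouping:
    """The grouping the generator planted (matches simulate_dataset ids)."""
    assignment = {f"mig{i:03d}": MIGRATORY for i in range(cfg.n_migratory)}
    assignment.update({f"fw{i:03d}": FRESHWATER for i in range(cfg.n_freshwater)})
    return SampleGrouping(assignment=assignment)


def simulate_annotation(cfg: SimulationConfig, seed: int | None = None,
                        gene_length: int = 300,
                        gene_spacing: int = 5000) -> GeneAnnotation:
    """Place non-overlapping single-CDS genes at a regular period.

    One gene per ``gene_spacing + gene_length`` bp from the chromosome
    start, so any sweep interval at least one period long is guaranteed to
    overlap a gene.  Gene length must be a multiple of 3 (single CDS
    spanning the whole gene); strand is drawn at random.
    """
    if gene_length % 3 != 0:
        raise ValueError("gene_length must be a multiple of 3")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    period = gene_length + gene_spacing
    genes = []
    for chrom in cfg.chrom_lengths:
        length = cfg.chrom_lengths[chrom]
        n_genes = length // period
        for k in range(n_genes):
            start = k * period + 1
            end = start + gene_length - 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(
                gene_id=f"{chrom}_g{k:04d}", chrom=chrom, start=start,
                end=end, strand=strand, cds=((start, end),)))
    return GeneAnnotation(genes=genes)


def reference_for(ds: GenotypeDataset, chrom_lengths: dict[str, int],
                  seed: int = 0) -> dict[str, str]:
    """A random reference genome consistent with the dataset's ref alleles."""
    rng = np.random.default_rng(seed)
    seqs = {}
    for chrom, length in chrom_lengths.items():
        arr = _BASES[rng.integers(0, 4, size=length)].copy()
        sub = ds.sites[ds.sites["chrom"] == chrom]
        arr[sub["pos"].to_numpy() - 1] = sub["ref"].to_numpy()
        seqs[chrom] = "".join(arr)
    return seqs


# ---------------------------------------------------------------------------
# Otolith transects

def simulate_otolith(pattern: str, n_points: int = 60, noise_sd: float = 0.3,
                     seed: int = 0) -> pd.DataFrame:
    """Simulate a core->edge otolith Sr:Ca transect.

    ``resident`` transects sit at the freshwater mean (1.5) throughout;
    ``migratory`` transects start with a freshwater core (first third)
    followed by alternating brackish (5.0) and seawater (8.0) segments,
    mimicking repeated movement between water masses.  Gaussian noise of
    ``noise_sd`` is added and values are clipped at 0.
    """
    if n_points < 10:
        raise ValueError("need at least 10 transect points")
    if pattern not in {"resident", "migratory"}:
        raise ValueError(f"unknown pattern {pattern!r}")
    rng = np.random.default_rng(seed)
    means = np.full(n_points, 1.5)
    if pattern == "migratory":
        core = n_points // 3
        seg = max(5, (n_points - core) // 4)
        level = 0
        for start in range(core, n_points, seg):
            means[start:start + seg] = 5.0 if level % 2 == 0 else 8.0
            level += 1
    ratios = means + rng.normal(0.0, noise_sd, size=n_points)
    ratios = np.clip(ratios, 0.0, None)
    return pd.DataFrame({
        "distance_um": np.arange(n_points, dtype=float) * 10.0,
        "sr_ca_ratio": ratios})


# ---------------------------------------------------------------------------
# qPCR tables

def simulate_qpcr(n_per_group: int = 5, effect_log2: float = 2.0,
                  seed: int = 0, gene: str = "target",
                  baseline_dct: float = 8.0) -> pd.DataFrame:
    """Simulate a relative-quantification qPCR experiment.

    Reference-gene Ct ~ Normal(15, 0.2); target Ct = reference Ct +
    ``baseline_dct`` - ``effect_log2`` x 1[migratory] + Normal(0, 0.3),
    so migratory samples express the target ``2**effect_log2``-fold
    higher than freshwater residents on average.
    """
    if n_per_group < 3:
        raise ValueError("need at least 3 samples per group")
    rng = np.random.default_rng(seed)
    rows = []
    for group in (MIGRATORY, FRESHWATER):
        shift = effect_log2 if group == MIGRATORY else 0.0
        for i in range(n_per_group):
            ct_ref = rng.normal(15.0, 0.2)
            ct_tgt = ct_ref + baseline_dct - shift + rng.normal(0.0, 0.3)
            rows.append({"sample_id": f"{group[:3]}{i}", "group": group,
                         "gene": gene, "ct_target": ct_tgt,
                         "ct_reference": ct_ref})
    return pd.DataFrame(rows)


def config_to_dict(cfg: SimulationConfig) -> dict:
    d = asdict(cfg)
    d["sweep_intervals"] = [list(t) for t in d["sweep_intervals"]]
    return d
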