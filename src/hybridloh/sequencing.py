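"""Simulators for the observable data layers.

Given a diploid genome with per-SNP allele copy counts, these functions
emit the inputs consumed by the callers: allele-specific read counts,
two-channel microarray ratios, alkaline-fragmentation samples (the
alkali cleaves the backbone at embedded ribonucleotides), rDNA coverage,
and mutation/SNP read co-observations used for haplotype linkage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._util import rng_from
from .errors import ParameterError
from .genome import DiploidGenome


def simulate_allele_counts(genome: DiploidGenome, mean_depth: float = 30.0,
                           overdispersion: float = 0.0, seed=None,
                           exact: bool = False) -> pd.DataFrame:
    """Sample per-SNP allele-specific read counts.

    Total depth at a site is Poisson around ``mean_depth`` scaled by the
    local total copy number over two; the W-allele count is binomial with
    probability equal to the W copy fraction (beta-binomial when
    ``overdispersion`` > 0, parameterized so the intraclass correlation
    equals the overdispersion).  ``exact=True`` replaces sampling by the
    rounded expectations, giving a noise-free table.
    """
    if mean_depth <= 0:
        raise ParameterError("mean depth must be positive")
    if overdispersion < 0:
        raise ParameterError("overdispersion must be non-negative")
    rng = rng_from(seed)
    hapW, hapY = genome.config.haplotypes
    snps = genome.snps
    n_w = snps[f"n_{hapW}"].to_numpy()
    n_y = snps[f"n_{hapY}"].to_numpy()
    copy_total = n_w + n_y
    lam = mean_depth * copy_total / 2.0
    with np.errstate(invalid="ignore"):
        p_w = np.where(copy_total > 0, n_w / np.maximum(copy_total, 1), 0.0)

    if exact:
        total = np.round(lam).astype(np.int64)
        count_w = np.round(total * p_w).astype(np.int64)
    else:
        total = rng.poisson(lam)
        if overdispersion > 0:
            conc = 1.0 / overdispersion - 1.0
            p_eff = np.where(
                (p_w > 0) & (p_w < 1),
                rng.beta(np.maximum(p_w * conc, 1e-12), np.maximum((1 - p_w) * conc, 1e-12)),
                p_w,
            )
        else:
            p_eff = p_w
        count_w = rng.binomial(total, p_eff)
    count_y = total - count_w

    return pd.DataFrame({
        "chrom": snps["chrom"],
        "pos": snps["pos"],
        f"allele_{hapW}": snps[f"allele_{hapW}"],
        f"allele_{hapY}": snps[f"allele_{hapY}"],
        f"count_{hapW}": count_w.astype(np.int64),
        f"count_{hapY}": count_y.astype(np.int64),
    })


def simulate_microarray_ratios(genome: DiploidGenome, noise_sd: float = 0.0,
                               seed=None) -> pd.DataFrame:
    """Two-channel probe ratios: one allele-specific probe per SNP per haplotype.

    The raw ratio of each probe is proportional to the copy number of the
    targeted allele (a heterozygous disomic site gives 1 against the
    isogenic control); the returned ``r_m`` column is re-centered by the
    genome-wide mean so that mean(r_m) is exactly 1.
    """
    if noise_sd < 0:
        raise ParameterError("noise sd must be non-negative")
    rng = rng_from(seed)
    hapW, hapY = genome.config.haplotypes
    snps = genome.snps
    frames = []
    for hap in (hapW, hapY):
        copy = snps[f"n_{hap}"].to_numpy(dtype=float)
        raw = copy + (rng.normal(0.0, noise_sd, size=len(copy)) if noise_sd > 0 else 0.0)
        raw = np.clip(raw, 0.0, None)
        frames.append(pd.DataFrame({
            "probe_id": [f"{c}:{p}:{hap}" for c, p in zip(snps["chrom"], snps["pos"])],
            "chrom": snps["chrom"],
            "pos": snps["pos"],
            "target": hap,
            "r_raw": raw,
        }))
    probes = pd.concat(frames, ignore_index=True)
    mean_raw = probes["r_raw"].mean()
    if mean_raw == 0:
        raise ParameterError("all probe signals are zero; cannot center")
    probes["r_m"] = probes["r_raw"] / mean_raw
    return probes


def simulate_alkaline_fragments(molecule_length: int, rnmp_density: float,
                                n_molecules: int = 1, seed=None) -> np.ndarray:
    """Alkaline-cleavage fragment lengths for rNMP-containing molecules.

    Cleavage sites are a Poisson process along each molecule at
    ``rnmp_density`` per bp; fragments are the gaps between sites (and
    the molecule ends).  Density 0 returns intact molecules.
    """
    if molecule_length <= 0:
        raise ParameterError("molecule length must be positive")
    if rnmp_density < 0:
        raise ParameterError("rNMP density must be non-negative")
    if n_molecules <= 0:
        raise ParameterError("need at least one molecule")
    rng = rng_from(seed)
    if rnmp_density == 0:
        return np.full(n_molecules, float(molecule_length))
    fragments = []
    n_cuts = rng.poisson(rnmp_density * molecule_length, size=n_molecules)
    for k in n_cuts:
        if k == 0:
            fragments.append(np.array([float(molecule_length)]))
            continue
        cuts = np.sort(rng.uniform(0, molecule_length, size=k))
        edges = np.concatenate(([0.0], cuts, [float(molecule_length)]))
        fragments.append(np.diff(edges))
    return np.concatenate(fragments)


def simulate_rdna_coverage(repeats_w: int, repeats_y: int, mean_depth: float = 50.0,
                           n_rdna_sites: int = 200, n_baseline_sites: int = 2000,
                           seed=None) -> dict:
    """Read coverage over the rDNA array and a single-copy baseline.

    Single-copy (disomic) sites are covered at Poisson(``mean_depth``);
    each position of the repeat unit is covered proportionally to the
    total repeat number over the two repeats a disomic locus would carry.
    Haplotype-specific read counts at rDNA-internal SNPs split the array
    coverage by repeat fraction.
    """
    if mean_depth <= 0:
        raise ParameterError("depth must be positive")
    if repeats_w < 0 or repeats_y < 0:
        raise ParameterError("repeat counts must be non-negative")
    rng = rng_from(seed)
    baseline = rng.poisson(mean_depth, size=n_baseline_sites)
    total_repeats = repeats_w + repeats_y
    rdna = rng.poisson(mean_depth * total_repeats / 2.0, size=n_rdna_sites)
    if total_repeats > 0:
        w_counts = rng.binomial(rdna, repeats_w / total_repeats)
    else:
        w_counts = np.zeros_like(rdna)
    return {
        "baseline": baseline,
        "rdna": rdna,
        "rdna_w": w_counts,
        "rdna_y": rdna - w_counts,
    }


def simulate_co_observations(mutations: pd.DataFrame, snps: pd.DataFrame,
                             mean_depth: float = 30.0, window: int = 300,
                             seed=None) -> pd.DataFrame:
    """Read co-observations of mutant bases with nearby heterozygous SNPs.

    For each mutation (columns chrom, pos, target) the nearest marker
    within ``window`` bp is found; the number of reads spanning both
    sites falls off linearly with distance (a read/fragment of roughly
    ``window`` bp), and every spanning read reports the allele of the
    carrier haplotype.  Output columns: chrom, mut_pos, snp_pos,
    haplotype, n_reads.
    """
    rng = rng_from(seed)
    rows = []
    for _, mut in mutations.iterrows():
        chrom_snps = snps[snps["chrom"] == mut["chrom"]]
        if chrom_snps.empty:
            continue
        dist = (chrom_snps["pos"] - mut["pos"]).abs()
        j = dist.idxmin()
        d = int(dist.loc[j])
        if d > window:
            continue
        span_p = max(0.0, 1.0 - d / window)
        n = int(rng.binomial(max(1, int(round(mean_depth))), span_p))
        if n == 0:
            continue
        rows.append((mut["chrom"], int(mut["pos"]), int(chrom_snps.loc[j, "pos"]),
                     mut["target"], n))
    return pd.DataFrame(rows, columns=["chrom", "mut_pos", "snp_pos", "haplotype", "n_reads"])
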