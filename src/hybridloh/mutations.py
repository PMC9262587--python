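"""Annotation and context statistics for de novo SNVs and small in/dels.

Covers haplotype linkage of mutations to nearby phased markers (short-
read linkage is only observable within ~300 bp), the 5'-flanking-base
composition test (a ribonucleotide-driven origin predicts an excess of
mutations 3' of C), the six-class substitution spectrum with
complementary collapsing, classification of short deletions inside
dinucleotide runs (the footprint of topoisomerase-mediated ribonucleotide
removal), and the mixed-read (subclonal) filter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import COMPLEMENT
from .errors import InputError

logger = logging.getLogger(__name__)

SIX_CLASSES = ("C:G>T:A", "C:G>A:T", "C:G>G:C", "T:A>C:G", "T:A>A:T", "T:A>G:C")

_PYRIMIDINE = {"C", "T"}


@dataclass(frozen=True)
class ContextParams:
    """Tunable context parameters.

    ``expected_5p_c`` is the fraction of 5' flanks expected to be C under
    a random association; it is a parameter (default 0.35) rather than a
    quantity derived from the G+C content, because more than one counting
    convention is compatible with a 38% G+C genome.
    """

    linkage_window: int = 300
    gc_content: float = 0.38
    expected_5p_c: float = 0.35
    mixed_read_threshold: float = 0.70
    min_run_units: int = 2

    def __post_init__(self):
        if self.linkage_window <= 0:
            raise InputError("linkage window must be positive")
        for name in ("gc_content", "expected_5p_c", "mixed_read_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise InputError(f"{name} must lie in (0, 1)")


# ---------------------------------------------------------------------------
# haplotype linkage

def link_to_haplotype(chrom: str, pos: int, snps: pd.DataFrame,
                      co_observations: pd.DataFrame, window: int = 300,
                      min_concordant: int = 2) -> str:
    """Assign a mutation to the haplotype its reads co-travel with.

    The mutation is linked to a haplotype when a heterozygous marker lies
    within ``window`` bp and at least ``min_concordant`` reads co-observe
    the mutant base with that haplotype's allele, with no discordant
    reads; conflicting co-observations yield ``'unlinked'`` with a
    warning, as does the absence of a marker in range.
    """
    near = snps[(snps["chrom"] == chrom) & ((snps["pos"] - pos).abs() <= window)]
    if near.empty:
        return "unlinked"
    obs = co_observations[(co_observations["chrom"] == chrom)
                          & (co_observations["mut_pos"] == pos)
                          & (co_observations["snp_pos"].isin(near["pos"]))]
    if obs.empty:
        return "unlinked"
    by_hap = obs.groupby("haplotype")["n_reads"].sum()
    positive = by_hap[by_hap > 0]
    if len(positive) > 1:
        warnings.warn(f"conflicting linkage co-observations at {chrom}:{pos}; "
                      "reporting unlinked")
        return "unlinked"
    hap = positive.index[0]
    if positive.iloc[0] < min_concordant:
        return "unlinked"
    return str(hap)


def link_mutations(mutations: pd.DataFrame, snps: pd.DataFrame,
                   co_observations: pd.DataFrame, window: int = 300,
                   min_concordant: int = 2) -> pd.DataFrame:
    """Vectorized convenience wrapper: adds a ``linked`` column."""
    out = mutations.copy()
    out["linked"] = [
        link_to_haplotype(row["chrom"], int(row["pos"]), snps, co_observations,
                          window=window, min_concordant=min_concordant)
        for _, row in mutations.iterrows()
    ]
    return out


# ---------------------------------------------------------------------------
# 5' context

def five_prime_context_counts(observed_c: int, denominator: int,
                              expected_fraction: float = 0.35) -> dict:
    """Chi-square comparison of an observed 5'C count against expectation.

    One-degree-of-freedom chi-square of (C, not-C) counts against the
    expected split.  Returns observed/expected percentages alongside the
    statistic and p-value.
    """
    if denominator <= 0:
        raise InputError("denominator must be positive")
    if not (0 <= observed_c <= denominator):
        raise InputError("observed count outside [0, denominator]")
    exp_c = expected_fraction * denominator
    f_obs = np.array([observed_c, denominator - observed_c], dtype=float)
    f_exp = np.array([exp_c, denominator - exp_c], dtype=float)
    chi2, p = stats.chisquare(f_obs, f_exp)
    return {
        "observed_c": int(observed_c),
        "denominator": int(denominator),
        "observed_pct": 100.0 * observed_c / denominator,
        "expected_pct": 100.0 * expected_fraction,
        "chi2": float(chi2),
        "p": float(p),
    }


def five_prime_context(snvs: pd.DataFrame, sequences: dict,
                       params: ContextParams = ContextParams()) -> dict:
    """Count 5'-flanking C in both strand orientations for a set of SNVs.

    Each SNV contributes two observations: the base 5' of the site on the
    plus strand, and the base 5' on the minus strand (the complement of
    the base 3' on the plus strand), so the denominator is twice the
    number of SNVs with both flanks defined.  Orientations lacking a
    flank (chromosome termini) are skipped and logged.
    """
    obs_c = 0
    denom = 0
    skipped = 0
    for _, row in snvs.iterrows():
        seq = sequences[row["chrom"]]
        pos = int(row["pos"])  # 1-based
        if pos >= 2:
            denom += 1
            if seq[pos - 2].upper() == "C":
                obs_c += 1
        else:
            skipped += 1
        if pos <= len(seq) - 1:
            denom += 1
            if COMPLEMENT[seq[pos].upper()] == "C":
                obs_c += 1
        else:
            skipped += 1
    if skipped:
        logger.info("five_prime_context: %d orientation(s) lacked a flank and were skipped",
                    skipped)
    result = five_prime_context_counts(obs_c, denom, params.expected_5p_c)
    result["skipped_orientations"] = skipped
    return result


# ---------------------------------------------------------------------------
# substitution spectrum

def substitution_class(ref: str, alt: str) -> str:
    """Collapse a substitution onto the six pyrimidine-anchored classes."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in "ACGT" or alt not in "ACGT" or ref == alt:
        raise InputError(f"not a substitution: {ref}>{alt}")
    if ref not in _PYRIMIDINE:
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    pair = {"C": ("C:G", {"T": "T:A", "A": "A:T", "G": "G:C"}),
            "T": ("T:A", {"C": "C:G", "A": "A:T", "G": "G:C"})}
    left, right_map = pair[ref]
    return f"{left}>{right_map[alt]}"


def classify_substitutions(snvs: pd.DataFrame) -> pd.Series:
    """Six-class spectrum (counts) of an SNV table with ref/alt columns."""
    if len(snvs) == 0:
        raise InputError("empty SNV set")
    counts = pd.Series(0, index=list(SIX_CLASSES), dtype=int)
    for _, row in snvs.iterrows():
        counts[substitution_class(row["ref"], row["alt"])] += 1
    return counts


def spectrum_test(counts_a: pd.Series, counts_b: pd.Series) -> dict:
    """Compare two substitution spectra.

    Fisher's exact test is used for 2x2 tables; larger tables fall back
    to the chi-square test of independence (the choice is logged).
    """
    a = counts_a
    b = counts_b.reindex(a.index, fill_value=0)
    table = np.vstack([a.to_numpy(), b.to_numpy()])
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] == 2:
        _, p = stats.fisher_exact(table)
        method = "fisher"
        statistic = float("nan")
    else:
        if np.array_equal(table[0], table[1]):
            statistic, p = 0.0, 1.0
        else:
            statistic, p, _, _ = stats.chi2_contingency(table)
        method = "chi2"
    logger.info("spectrum_test used %s on a 2x%d table", method, table.shape[1])
    return {"statistic": float(statistic), "p": float(p), "method": method}


# ---------------------------------------------------------------------------
# in/del run classification

def indel_run_classifier(chrom: str, pos: int, ref: str, alt: str,
                         sequences: dict, min_run_units: int = 2) -> dict:
    """Classify a deletion by size class and dinucleotide-run context.

    A 2 bp deletion whose deleted unit is part of a tandem dinucleotide
    run of at least ``min_run_units`` copies (including the deleted copy)
    is flagged as a run deletion — the signature expected from
    topoisomerase-mediated removal of embedded ribonucleotides.  Run
    logic applies only to 2 bp deletions; size class distinguishes 1-3 bp
    deletions from larger ones.
    """
    if len(alt) >= len(ref):
        return {"is_deletion": False, "size_class": "", "run": False, "unit": ""}
    deleted = ref[len(alt):] if ref.startswith(alt) else ref
    size = len(deleted)
    size_class = "1-3" if size <= 3 else ">3"
    result = {"is_deletion": True, "size": size, "size_class": size_class,
              "run": False, "unit": ""}
    if size != 2:
        return result
    seq = sequences[chrom]
    start0 = pos - 1 + len(alt)          # 0-based start of the deleted unit
    unit = seq[start0:start0 + 2].upper()
    if unit != deleted.upper():
        unit = deleted.upper()
    copies = 1
    i = start0 - 2
    while i >= 0 and seq[i:i + 2].upper() == unit:
        copies += 1
        i -= 2
    i = start0 + 2
    while i + 2 <= len(seq) and seq[i:i + 2].upper() == unit:
        copies += 1
        i += 2
    if copies >= min_run_units:
        result["run"] = True
        result["unit"] = unit
        result["copies"] = copies
    return result


# ---------------------------------------------------------------------------
# mixed-read filter

def mixed_read_filter(mutations: pd.DataFrame, threshold: float = 0.70,
                      het_band=(0.35, 0.65)) -> pd.DataFrame:
    """Partition mutations into clonal and mixed (subclonal) sets.

    In a haploid context a clonal mutation should be supported by nearly
    all reads: fractions strictly above ``threshold`` are clonal, anything
    at or below is mixed.  In a diploid context a clonal heterozygous
    mutation sits near 0.5, so the mixed label applies below the
    heterozygous band.
    """
    out = mutations.copy()
    frac = out["fraction"].astype(float)
    if (frac < 0).any() or (frac > 1).any():
        raise InputError("read fractions must lie in [0, 1]")
    ploidy = out.get("ploidy_context", pd.Series("haploid", index=out.index))
    labels = []
    for f, pl in zip(frac, ploidy):
        if pl == "diploid":
            labels.append("mixed" if f < het_band[0] else "clonal")
        else:
            labels.append("clonal" if f > threshold else "mixed")
    out["clonality"] = labels
    return out
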