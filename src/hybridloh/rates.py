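"""Rate, fold-change, expectation and enrichment statistics.

These are the desk-scale quantitative summaries of a genome-instability
experiment: per-division event rates from event counts over isolates and
divisions, fold changes over wild-type baselines, the extrapolation from
inter-homolog repair events to total double-strand breaks via the
sister-chromatid repair ratio, the expected number of LOH events covering
a locus from its genome fraction, breakpoint-vs-element enrichment with
multiple-testing correction and a permutation oracle, Fisher's exact test
for viability tables, and a tandem-repeat finder used to build the
tandem-repeat annotation class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import merge_intervals, rng_from, round_sig
from .errors import InputError, ParameterError


@dataclass(frozen=True)
class RateBaselines:
    """Wild-type baselines and colony-growth constants.

    All rates are per cell division.  ``divisions_per_colony`` is the
    number of divisions needed to grow a single cell into a colony;
    ``sister_ratio`` is how much more often a DSB is repaired off the
    sister chromatid than off the homolog (only inter-homolog repair is
    visible as LOH).
    """

    wt_loh_rate: float = 4.6e-3
    wt_upd_rate: float = 4e-6
    divisions_per_colony: int = 25
    sister_ratio: float = 20.0

    def __post_init__(self):
        for name in ("wt_loh_rate", "wt_upd_rate", "divisions_per_colony", "sister_ratio"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")


def event_rate(n_events: int, n_isolates: int, divisions: float) -> float:
    """Events per cell division: n_events / (n_isolates x divisions)."""
    if n_events < 0:
        raise ParameterError("event count must be non-negative")
    if n_isolates <= 0 or divisions <= 0:
        raise ParameterError("isolates and divisions must be positive")
    return n_events / (n_isolates * divisions)


@dataclass(frozen=True)
class FoldChange:
    raw: float
    rounded: float


def fold_change(rate: float, baseline: float, digits: int = 2) -> FoldChange:
    """Fold elevation of a rate over a baseline, raw and at two significant figures."""
    if baseline <= 0:
        raise ParameterError("baseline must be positive")
    raw = rate / baseline
    return FoldChange(raw=raw, rounded=round_sig(raw, digits))


def dsb_extrapolation(events_per_isolate: float, sister_ratio: float = 20.0) -> float:
    """Total DSBs per isolate implied by the visible inter-homolog events.

    Only inter-homolog repair produces LOH; multiplying by the
    sister:homolog repair ratio estimates all breaks.
    """
    if sister_ratio < 0:
        raise ParameterError("sister ratio must be non-negative")
    return events_per_isolate * sister_ratio


def locus_loh_expectation(n_tloh: int, genome_fraction: float,
                          observed: int | None = None) -> dict:
    """Expected number of terminal LOH events covering a locus.

    With breakpoints spread uniformly, a locus spanning ``genome_fraction``
    of the genome should be covered by ``n_tloh x genome_fraction``
    events.  When an observed count is given, a one-degree-of-freedom
    chi-square on (covering, not covering) and an exact two-sided Poisson
    test are reported.
    """
    if not (0.0 <= genome_fraction <= 1.0):
        raise ParameterError("genome fraction must lie in [0, 1]")
    expected = n_tloh * genome_fraction
    out = {"expected": expected, "expected_rounded": int(round(expected))}
    if observed is not None:
        if expected in (0.0,) or expected == n_tloh:
            out["chi2"], out["p_chi2"] = float("nan"), float("nan")
        else:
            f_obs = np.array([observed, n_tloh - observed], dtype=float)
            f_exp = np.array([expected, n_tloh - expected], dtype=float)
            chi2, p = stats.chisquare(f_obs, f_exp)
            out["chi2"], out["p_chi2"] = float(chi2), float(p)
        pois = stats.poisson(expected if expected > 0 else 1e-12)
        p_lo = pois.cdf(observed)
        p_hi = pois.sf(observed - 1)
        out["p_poisson"] = float(min(1.0, 2.0 * min(p_lo, p_hi)))
    return out


# ---------------------------------------------------------------------------
# breakpoint-element enrichment

def element_enrichment(breakpoints: pd.DataFrame, annotation: pd.DataFrame,
                       chromosome_lengths: dict, tolerance: int = 1000,
                       alpha: float = 0.05, correction: str = "bonferroni",
                       n_permutations: int = 0, seed=None) -> pd.DataFrame:
    """Per-class over-representation of breakpoints at annotated elements.

    For each element class, the observed number of breakpoint midpoints
    falling within ``tolerance`` of a class interval is compared with the
    expectation from the class's genomic footprint (merged padded
    intervals / genome length) by Fisher's exact test on the 2x2 table of
    overlapping vs non-overlapping breakpoints against the expected split.
    When ``n_permutations`` > 0, an empirical p-value from uniform
    re-placement of the breakpoints is reported alongside as an oracle.
    Classes with zero genomic footprint are skipped with a warning.
    p-values are corrected across classes (Bonferroni by default,
    Benjamini-Hochberg via ``correction='bh'``).
    """
    if len(breakpoints) == 0:
        raise InputError("empty breakpoint list")
    if not len(annotation):
        raise InputError("empty annotation")
    genome_len = float(sum(chromosome_lengths.values()))
    n = len(breakpoints)
    rng = rng_from(seed)

    padded = {}
    for cls, grp in annotation.groupby("cls", observed=True):
        per_chrom = {}
        footprint = 0
        for chrom, sub in grp.groupby("chrom", observed=True):
            clen = chromosome_lengths.get(chrom)
            if clen is None:
                continue
            ivs = merge_intervals([(max(1, s - tolerance), min(clen, e + tolerance))
                                   for s, e in zip(sub["start"], sub["end"])])
            per_chrom[chrom] = ivs
            footprint += sum(b - a + 1 for a, b in ivs)
        padded[cls] = (per_chrom, footprint)

    def count_overlaps(cls_ivs, chroms, positions):
        hits = 0
        for chrom in np.unique(chroms):
            ivs = cls_ivs.get(chrom)
            if not ivs:
                continue
            starts = np.array([a for a, _ in ivs])
            ends = np.array([b for _, b in ivs])
            pos = positions[chroms == chrom]
            idx = np.searchsorted(starts, pos, side="right") - 1
            ok = idx >= 0
            hits += int(np.count_nonzero(pos[ok] <= ends[idx[ok]]))
        return hits

    bp_chroms = np.asarray(breakpoints["chrom"], dtype=object)
    bp_pos = np.asarray(breakpoints["pos"], dtype=np.int64)

    perm_positions = None
    if n_permutations > 0:
        names = np.array(list(chromosome_lengths), dtype=object)
        lens = np.array([chromosome_lengths[c] for c in names], dtype=float)
        pchoice = lens / lens.sum()
        perm_positions = []
        for _ in range(n_permutations):
            ci = rng.choice(len(names), size=n, p=pchoice)
            pos = (rng.random(n) * lens[ci]).astype(np.int64) + 1
            perm_positions.append((names[ci], pos))

    rows = []
    for cls, (cls_ivs, footprint) in padded.items():
        if footprint == 0:
            warnings.warn(f"element class {cls!r} has zero genomic footprint; skipped")
            continue
        frac = footprint / genome_len
        obs = count_overlaps(cls_ivs, bp_chroms, bp_pos)
        expected = n * frac
        exp_count = int(round(expected))
        table = [[obs, n - obs], [exp_count, n - exp_count]]
        _, p_fisher = stats.fisher_exact(table, alternative="greater")
        row = {"cls": cls, "n_breakpoints": n, "observed": obs,
               "footprint_fraction": frac, "expected": expected,
               "p": float(p_fisher)}
        if perm_positions is not None:
            exceed = sum(count_overlaps(cls_ivs, ch, po) >= obs
                         for ch, po in perm_positions)
            row["p_perm"] = (1 + exceed) / (n_permutations + 1)
        rows.append(row)

    result = pd.DataFrame(rows)
    k = len(result)
    if correction == "bonferroni":
        result["p_corrected"] = np.minimum(result["p"] * k, 1.0)
    elif correction == "bh":
        p = result["p"].to_numpy()
        order = np.argsort(p)
        ranked = p[order] * k / (np.arange(k) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        corrected = np.empty(k)
        corrected[order] = np.minimum(adj, 1.0)
        result["p_corrected"] = corrected
    else:
        raise ParameterError(f"unknown correction {correction!r}")
    result["significant"] = result["p_corrected"] < alpha
    return result.sort_values("p", ignore_index=True)


# ---------------------------------------------------------------------------
# Fisher exact for viability tables

def viability_fisher(table) -> dict:
    """Two-sided Fisher's exact test on a 2x2 viable/inviable table."""
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise InputError("need a 2x2 table of non-negative integers")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise InputError("a margin of the table is all zero")
    odds, p = stats.fisher_exact(arr, alternative="two-sided")
    return {"odds_ratio": float(odds), "p": float(p)}


# ---------------------------------------------------------------------------
# tandem repeats

def find_tandem_repeats(sequence: str, min_region: int = 24,
                        unit_range=(1, 1998), min_units: int = 2) -> pd.DataFrame:
    """Maximal tandem-repeat regions (1-based inclusive coordinates).

    A region qualifies when it spans at least ``min_region`` bp and
    consists of at least ``min_units`` adjacent copies of a unit whose
    size lies within ``unit_range`` (a trailing partial copy counts
    toward the span).  Regions wholly contained in a region of smaller
    unit size (e.g. the period-4 reading of a dinucleotide run) are
    suppressed.
    """
    if not sequence:
        raise InputError("empty sequence")
    s = np.frombuffer(sequence.upper().encode(), dtype=np.uint8)
    L = len(s)
    lo, hi = unit_range
    found = []
    for k in range(max(1, lo), min(hi, L // min_units) + 1):
        eq = s[: L - k] == s[k:]
        if not eq.any():
            continue
        # runs of consecutive matches of length m give a region of m + k bp
        idx = np.flatnonzero(np.diff(np.concatenate(([0], eq.view(np.int8), [0]))))
        for a, b in zip(idx[::2], idx[1::2]):
            m = b - a
            span = m + k
            if span < min_region or span < min_units * k:
                continue
            start, end = a + 1, a + span  # 1-based inclusive
            contained = any(ps <= start and end <= pe for ps, pe, pk in found if pk < k)
            if not contained:
                found.append((start, end, k))
    df = pd.DataFrame(found, columns=["start", "end", "unit_size"])
    if len(df):
        df["unit"] = [sequence[a - 1:a - 1 + k].upper() for a, k in zip(df["start"], df["unit_size"])]
        df["copies"] = (df["end"] - df["start"] + 1) / df["unit_size"]
    else:
        df["unit"] = pd.Series(dtype=str)
        df["copies"] = pd.Series(dtype=float)
    return df.sort_values(["start", "unit_size"], ignore_index=True)
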