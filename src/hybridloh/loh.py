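"""Loss-of-heterozygosity calling from allele-specific SNP read counts.

Pipeline
--------
1. :func:`compute_rc` converts allele-specific counts into ratio-of-
   coverage (RC) values: per-allele count divided by the genome-wide mean
   per-site total count, so one allele copy sits near 0.5, two copies
   near 1.0 and a lost allele near 0.
2. :func:`call_genotype_states` classifies each marker as heterozygous or
   homozygous-for-one-parent by RC band membership and segments each
   chromosome, requiring a minimum run of concordant markers to open a
   segment; isolated single-marker homozygosity is emitted as a flagged
   candidate rather than a segment break.
3. :func:`segment_to_events` turns homozygous segments into classified
   LOH events: terminal (T-LOH) when the tract reaches a chromosome end,
   interstitial (I-LOH) otherwise, with the class vocabulary CON (simple
   conversion), CON/CON (complex interstitial), CO/CON (terminal event
   with an associated interstitial tract) and CO/BIR-candidate (plain
   terminal event — a single colony cannot distinguish a reciprocal
   crossover from break-induced replication).
4. :func:`breakpoint_interval` brackets the recombination-initiating
   lesion between the last heterozygous and first homozygous marker.
5. :func:`compare_event_sets` matches event sets between subclones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConsistencyError, InputError, QualityError

STATE_HET = "het"
STATE_NA = "na"


@dataclass(frozen=True)
class Bands:
    """RC classification bands.

    A marker is heterozygous when both allele RCs fall inside
    ``[het_lo, het_hi]`` (band edges inclusive: ties resolve toward
    heterozygosity), homozygous for one parent when that allele's RC is
    at least ``hom_hi`` and the other's at most ``hom_lo``.  The idealized
    anchors are 0.5 for one copy, 1.0 for two and 0 for none.

    The default heterozygous band is [0.25, 0.75]: at a typical mean
    depth of 30 the two allele counts at a het site are independent
    Poisson(15) variates, so a narrower band (e.g. [0.35, 0.65]) would
    leave ~40% of unaltered het markers unclassified, while [0.25, 0.75]
    keeps that below ~10% and still cannot be reached by a true
    homozygous site (whose lost allele has RC 0).
    """

    het_lo: float = 0.25
    het_hi: float = 0.75
    hom_hi: float = 0.80
    hom_lo: float = 0.15

    def __post_init__(self):
        if not (self.hom_lo < self.het_lo < self.het_hi < self.hom_hi):
            raise InputError("bands must be disjoint: hom_lo < het_lo < het_hi < hom_hi")


@dataclass
class Breakpoint:
    """Half-open breakpoint interval (lo, hi] between the last het and
    first hom marker on one side of an event."""

    side: str            # 'left' or 'right'
    lo: int
    hi: int
    clipped: bool = False

    @property
    def midpoint(self) -> float:
        return (self.lo + self.hi) / 2.0


@dataclass
class LohEvent:
    chrom: str
    loh_type: str            # 'I-LOH' or 'T-LOH'
    cls: str                 # CON, CON/CON, CO/CON, CO/BIR-candidate, UPD-candidate
    complexity: str          # 'simple' or 'complex'
    retained: str            # haplotype whose alleles remain
    recipient: str           # haplotype whose alleles were lost (lesion carrier)
    start_pos: int
    end_pos: int
    n_snps: int
    touches_start: bool
    touches_end: bool
    whole_chromosome: bool = False
    single_snp: bool = False
    breakpoints: list = field(default_factory=list)

    @property
    def midpoint(self) -> float:
        """Midpoint of the proximal (first) breakpoint interval."""
        return self.breakpoints[0].midpoint if self.breakpoints else (
            (self.start_pos + self.end_pos) / 2.0)


def events_to_frame(events) -> pd.DataFrame:
    rows = []
    for ev in events:
        rows.append({
            "chrom": ev.chrom, "loh_type": ev.loh_type, "cls": ev.cls,
            "complexity": ev.complexity, "retained": ev.retained,
            "recipient": ev.recipient, "start": ev.start_pos, "end": ev.end_pos,
            "n_snps": ev.n_snps, "single_snp": ev.single_snp,
            "whole_chromosome": ev.whole_chromosome,
            "midpoint": ev.midpoint,
            "breakpoints": ";".join(f"{b.side}:{b.lo}-{b.hi}" for b in ev.breakpoints),
        })
    cols = ["chrom", "loh_type", "cls", "complexity", "retained", "recipient",
            "start", "end", "n_snps", "single_snp", "whole_chromosome",
            "midpoint", "breakpoints"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# RC computation

def compute_rc(counts: pd.DataFrame, haplotypes=("W", "Y"),
               min_sites: int = 100) -> pd.DataFrame:
    """Add per-haplotype ratio-of-coverage columns to a count table.

    RC for an allele is its read count divided by the genome-wide mean
    per-site total count, so the expectation at an unaltered heterozygous
    site is 0.5 per allele.
    """
    hapW, hapY = haplotypes
    cw, cy = f"count_{hapW}", f"count_{hapY}"
    if cw not in counts or cy not in counts:
        raise InputError(f"count table must have columns {cw!r} and {cy!r}")
    if len(counts) < min_sites:
        raise InputError(f"need at least {min_sites} SNPs for stable RC normalization, "
                         f"got {len(counts)}")
    total = counts[cw] + counts[cy]
    mean_total = total.mean()
    if mean_total == 0:
        raise InputError("all counts are zero")
    out = counts.copy()
    out[f"rc_{hapW}"] = counts[cw] / mean_total
    out[f"rc_{hapY}"] = counts[cy] / mean_total
    return out


def rc_from_probes(probes: pd.DataFrame, haplotypes=("W", "Y")) -> pd.DataFrame:
    """Convert a centered two-channel probe table to the RC scale.

    Probe ratios are copy-proportional with a disomic heterozygous site at
    1; halving puts them on the RC scale (one copy = 0.5) so the same
    genotype caller serves both sequencing and array inputs.  Expects
    columns chrom, pos, target, r_m with one probe per haplotype per site.
    """
    hapW, hapY = haplotypes
    wide = probes.pivot_table(index=["chrom", "pos"], columns="target",
                              values="r_m", observed=True).reset_index()
    if hapW not in wide or hapY not in wide:
        raise InputError("probe table must target both haplotypes at each site")
    out = wide.rename(columns={hapW: f"rc_{hapW}", hapY: f"rc_{hapY}"})
    out[f"rc_{hapW}"] = out[f"rc_{hapW}"] / 2.0
    out[f"rc_{hapY}"] = out[f"rc_{hapY}"] / 2.0
    return out.sort_values(["chrom", "pos"], ignore_index=True)


# ---------------------------------------------------------------------------
# genotype-state segmentation

def _classify_states(rc_w, rc_y, bands: Bands, haplotypes):
    hapW, hapY = haplotypes
    states = np.full(len(rc_w), STATE_NA, dtype=object)
    het = ((rc_w >= bands.het_lo) & (rc_w <= bands.het_hi)
           & (rc_y >= bands.het_lo) & (rc_y <= bands.het_hi))
    hom_w = (rc_w >= bands.hom_hi) & (rc_y <= bands.hom_lo)
    hom_y = (rc_y >= bands.hom_hi) & (rc_w <= bands.hom_lo)
    states[het] = STATE_HET
    states[hom_w & ~het] = f"hom_{hapW}"
    states[hom_y & ~het] = f"hom_{hapY}"
    return states


def _rle(states):
    runs = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            runs.append([states[start], start, i - 1])
            start = i
    return runs


def _absorb_short_runs(runs, min_run):
    """Relabel runs shorter than ``min_run`` into a neighbor's state.

    Homozygous runs flanked by heterozygosity are recorded as flagged
    single-marker (or sub-threshold) candidates before being absorbed.
    """
    flagged = []
    runs = [list(r) for r in runs]
    while True:
        lengths = [r[2] - r[1] + 1 for r in runs]
        idx = None
        for i, ln in enumerate(lengths):
            if ln < min_run and len(runs) > 1:
                if idx is None or ln < lengths[idx]:
                    idx = i
        if idx is None:
            break
        state, s, e = runs[idx]
        prev = runs[idx - 1] if idx > 0 else None
        nxt = runs[idx + 1] if idx < len(runs) - 1 else None
        if state.startswith("hom") and (prev is None or prev[0] == STATE_HET) \
                and (nxt is None or nxt[0] == STATE_HET):
            flagged.append((state, s, e))
        if prev is None:
            new_state = nxt[0]
        elif nxt is None:
            new_state = prev[0]
        else:
            prev_len = prev[2] - prev[1] + 1
            nxt_len = nxt[2] - nxt[1] + 1
            new_state = prev[0] if prev_len >= nxt_len else nxt[0]
        runs[idx][0] = new_state
        merged = []
        for r in runs:
            if merged and merged[-1][0] == r[0]:
                merged[-1][2] = r[2]
            else:
                merged.append(r)
        runs = merged
    return runs, flagged


def call_genotype_states(snp_table: pd.DataFrame, bands: Bands = Bands(),
                         min_run: int = 2, haplotypes=("W", "Y"),
                         max_unclassified: float = 0.2):
    """Segment per-SNP zygosity states chromosome by chromosome.

    Returns ``(segments, flagged)``: a segment table (chrom, state,
    start/end marker index within the classified markers of the
    chromosome, bp span, marker count, mean RCs) and a table of flagged
    sub-threshold homozygous candidates (single aberrant markers).

    Raises :class:`QualityError` when more than ``max_unclassified`` of
    all markers fall outside every band.
    """
    hapW, hapY = haplotypes
    rcw, rcy = f"rc_{hapW}", f"rc_{hapY}"
    if rcw not in snp_table:
        raise InputError("snp table lacks RC columns; run compute_rc first")
    states_all = _classify_states(snp_table[rcw].to_numpy(),
                                  snp_table[rcy].to_numpy(), bands, haplotypes)
    frac_na = float(np.mean(states_all == STATE_NA))
    if frac_na > max_unclassified:
        offending = snp_table.loc[states_all == STATE_NA, ["chrom", "pos"]]
        raise QualityError(
            f"{frac_na:.1%} of markers unclassifiable (limit {max_unclassified:.0%})",
            offending_sites=offending)

    seg_rows, flag_rows = [], []
    for chrom in snp_table["chrom"].unique():
        sel = (snp_table["chrom"] == chrom).to_numpy()
        sub = snp_table.loc[sel]
        states = states_all[sel]
        keep = states != STATE_NA
        sub = sub.loc[keep]
        states = states[keep]
        if len(sub) == 0:
            continue
        pos = sub["pos"].to_numpy()
        rw = sub[rcw].to_numpy()
        ry = sub[rcy].to_numpy()
        runs, flagged = _absorb_short_runs(_rle(list(states)), min_run)
        for state, s, e in runs:
            seg_rows.append({
                "chrom": chrom, "state": state, "start_idx": s, "end_idx": e,
                "start_pos": int(pos[s]), "end_pos": int(pos[e]),
                "n_snps": e - s + 1,
                f"mean_rc_{hapW}": float(rw[s:e + 1].mean()),
                f"mean_rc_{hapY}": float(ry[s:e + 1].mean()),
            })
        for state, s, e in flagged:
            for i in range(s, e + 1):
                flag_rows.append({"chrom": chrom, "pos": int(pos[i]), "state": state,
                                  f"rc_{hapW}": float(rw[i]), f"rc_{hapY}": float(ry[i])})
    segments = pd.DataFrame(seg_rows, columns=[
        "chrom", "state", "start_idx", "end_idx", "start_pos", "end_pos",
        "n_snps", f"mean_rc_{hapW}", f"mean_rc_{hapY}"])
    flags = pd.DataFrame(flag_rows, columns=["chrom", "pos", "state",
                                             f"rc_{hapW}", f"rc_{hapY}"])
    return segments, flags


# ---------------------------------------------------------------------------
# events

def breakpoint_interval(last_het_pos: Optional[int], first_hom_pos: int,
                        side: str = "left") -> Breakpoint:
    """Bracket a breakpoint between flanking markers.

    The recombination-initiating lesion lies in the half-open interval
    ``(last het marker, first hom marker]``; when there is no proximal
    heterozygous marker (tract starts at the chromosome's first marker),
    the interval is clipped to the arm start and flagged.
    """
    if last_het_pos is None:
        return Breakpoint(side=side, lo=1, hi=int(first_hom_pos), clipped=True)
    lo, hi = int(last_het_pos), int(first_hom_pos)
    if lo > hi:
        lo, hi = hi, lo
    return Breakpoint(side=side, lo=lo, hi=hi, clipped=False)


def segment_to_events(segments: pd.DataFrame, merge_gap: int = 10,
                      haplotypes=("W", "Y"), flagged: Optional[pd.DataFrame] = None,
                      include_single_snp: bool = False) -> list:
    """Classify homozygous segments into LOH events.

    Homozygous segments separated by fewer than ``merge_gap`` heterozygous
    markers (or abutting directly) are merged into one complex event
    footprint.  A footprint touching a chromosome's terminal classified
    marker is a T-LOH (CO/BIR-candidate when it is a single block, CO/CON
    when an interstitial tract is associated); an interior footprint is
    I-LOH (CON or CON/CON).  A footprint covering the whole chromosome is
    marked as a UPD candidate pending a copy-number check.
    """
    hapW, hapY = haplotypes
    events = []
    for chrom, grp in segments.groupby("chrom", observed=True, sort=False):
        grp = grp.sort_values("start_idx").reset_index(drop=True)
        for i in range(1, len(grp)):
            if grp.loc[i, "state"] == grp.loc[i - 1, "state"]:
                raise ConsistencyError(f"adjacent segments share a state on {chrom}")
            if grp.loc[i, "start_idx"] != grp.loc[i - 1, "end_idx"] + 1:
                raise ConsistencyError(f"segments do not partition {chrom}")
        hom_idx = [i for i in range(len(grp)) if grp.loc[i, "state"].startswith("hom")]
        if not hom_idx:
            continue
        # group hom segments whose intervening het gap is below merge_gap
        groups = [[hom_idx[0]]]
        for i in hom_idx[1:]:
            prev = groups[-1][-1]
            het_between = int(grp.loc[prev + 1:i - 1, "n_snps"].sum())
            if het_between < merge_gap:
                groups[-1].append(i)
            else:
                groups.append([i])
        n_total_segments = len(grp)
        for g in groups:
            first, last = g[0], g[-1]
            blocks = [grp.loc[i] for i in g]
            touches_start = first == 0
            touches_end = last == n_total_segments - 1
            whole = touches_start and touches_end and len(g) == n_total_segments
            terminal = touches_start or touches_end
            n_blocks = len(blocks)
            has_internal_het = any(grp.loc[i, "state"] == STATE_HET
                                   for i in range(first, last + 1))
            # retained haplotype by marker majority over hom blocks
            w_snps = sum(int(b["n_snps"]) for b in blocks if b["state"] == f"hom_{hapW}")
            y_snps = sum(int(b["n_snps"]) for b in blocks if b["state"] == f"hom_{hapY}")
            retained = hapW if w_snps >= y_snps else hapY
            recipient = hapY if retained == hapW else hapW
            if whole:
                loh_type, cls = "T-LOH", "UPD-candidate"
            elif terminal:
                loh_type = "T-LOH"
                cls = "CO/CON" if (n_blocks > 1 or has_internal_het) else "CO/BIR-candidate"
            else:
                loh_type = "I-LOH"
                cls = "CON/CON" if (n_blocks > 1 or has_internal_het) else "CON"
            complexity = "simple" if (n_blocks == 1 and not has_internal_het) else "complex"

            bps = []
            if not touches_start:
                left_het = grp.loc[first - 1]
                bps.append(breakpoint_interval(int(left_het["end_pos"]),
                                               int(blocks[0]["start_pos"]), side="left"))
            else:
                bps.append(breakpoint_interval(None, int(blocks[0]["start_pos"]),
                                               side="left"))
            if not touches_end:
                right_het = grp.loc[last + 1]
                bps.append(Breakpoint(side="right", lo=int(blocks[-1]["end_pos"]),
                                      hi=int(right_het["start_pos"])))
            events.append(LohEvent(
                chrom=chrom, loh_type=loh_type, cls=cls, complexity=complexity,
                retained=retained, recipient=recipient,
                start_pos=int(blocks[0]["start_pos"]), end_pos=int(blocks[-1]["end_pos"]),
                n_snps=sum(int(b["n_snps"]) for b in blocks),
                touches_start=touches_start, touches_end=touches_end,
                whole_chromosome=whole, breakpoints=bps))

    if include_single_snp and flagged is not None and len(flagged):
        for _, row in flagged.iterrows():
            retained = row["state"].split("_", 1)[1]
            recipient = hapY if retained == hapW else hapW
            pos = int(row["pos"])
            events.append(LohEvent(
                chrom=row["chrom"], loh_type="I-LOH", cls="CON", complexity="simple",
                retained=retained, recipient=recipient, start_pos=pos, end_pos=pos,
                n_snps=1, touches_start=False, touches_end=False, single_snp=True,
                breakpoints=[Breakpoint("left", pos, pos)]))
    return events


def call_loh(counts: pd.DataFrame, bands: Bands = Bands(), min_run: int = 2,
             merge_gap: int = 10, haplotypes=("W", "Y"),
             include_single_snp: bool = False):
    """Full pipeline: counts -> RC -> segments -> classified events.

    Returns ``(events, segments, flagged)``.
    """
    rc = compute_rc(counts, haplotypes=haplotypes)
    segments, flagged = call_genotype_states(rc, bands=bands, min_run=min_run,
                                             haplotypes=haplotypes)
    events = segment_to_events(segments, merge_gap=merge_gap, haplotypes=haplotypes,
                               flagged=flagged, include_single_snp=include_single_snp)
    return events, segments, flagged


# ---------------------------------------------------------------------------
# subclone comparison

def compare_event_sets(events_a, events_b, tolerance: int = 10_000) -> dict:
    """Match two event sets from the same genome configuration.

    Events match when chromosome, LOH type and retained haplotype agree
    and the proximal-breakpoint midpoints lie within ``tolerance`` bp.
    Returns counts plus the matched pairs and private events.
    """
    used_b = set()
    shared = []
    for i, ea in enumerate(events_a):
        best = None
        for j, eb in enumerate(events_b):
            if j in used_b:
                continue
            if (ea.chrom, ea.loh_type, ea.retained) != (eb.chrom, eb.loh_type, eb.retained):
                continue
            d = abs(ea.midpoint - eb.midpoint)
            if d <= tolerance and (best is None or d < best[0]):
                best = (d, j)
        if best is not None:
            used_b.add(best[1])
            shared.append((ea, events_b[best[1]]))
    a_only = [ea for ea in events_a if not any(ea is pair[0] for pair in shared)]
    b_only = [eb for j, eb in enumerate(events_b) if j not in used_b]
    return {"shared": shared, "a_only": a_only, "b_only": b_only,
            "n_shared": len(shared), "n_a_only": len(a_only), "n_b_only": len(b_only)}
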