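"""Copy-number, uniparental disomy and structural-variant calling.

Coverage is summarized in non-overlapping windows (default 1 kb, matching
the marker spacing), normalized by the genome-wide median per-site total
so that a disomic heterozygous position has per-haplotype coverage ~1 and
total ~2.  The callers then look for whole-chromosome copy changes (UPD,
monosomy, trisomy), large (>5 kb) segmental deletions/duplications,
coupled terminal deletion/duplication pairs that predict a translocation,
and the haplotype-resolved rDNA repeat number from coverage ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .errors import InputError, PredictionError


@dataclass
class StructuralCall:
    kind: str                # UPD, monosomy, trisomy, interstitial deletion, ...
    chrom: str
    start: int
    end: int
    size: int
    haplotype: str = ""      # affected haplotype (lost/gained)
    chrom2: str = ""
    start2: int = 0
    end2: int = 0
    elements: str = ""
    note: str = ""


def calls_to_frame(calls) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in calls],
                        columns=["kind", "chrom", "start", "end", "size", "haplotype",
                                 "chrom2", "start2", "end2", "elements", "note"])


@dataclass
class CopyNumberProfile:
    """Windowed normalized coverage per haplotype plus per-chromosome calls."""

    windows: pd.DataFrame        # chrom, start, end, cov_W, cov_Y, cov_total
    chrom_means: pd.DataFrame    # chrom, cov_W, cov_Y, cov_total, call
    window_size: int
    haplotypes: tuple = ("W", "Y")


def copy_number_profile(counts: pd.DataFrame, window: int = 1000,
                        haplotypes=("W", "Y")) -> CopyNumberProfile:
    """Build a windowed copy-number profile from allele-specific counts.

    Per-haplotype coverage is normalized by half the genome-wide median
    per-site total, i.e. expressed in copy units (1 = one copy).  The
    median is robust to a handful of large CNVs.
    """
    hapW, hapY = haplotypes
    cw, cy = f"count_{hapW}", f"count_{hapY}"
    total = counts[cw] + counts[cy]
    med = float(total.median())
    if med <= 0:
        raise InputError("median per-site coverage is zero")
    per_copy = med / 2.0
    df = counts.copy()
    df["win"] = (df["pos"] - 1) // window
    agg = df.groupby(["chrom", "win"], observed=True).agg(
        n=("pos", "size"), sum_w=(cw, "sum"), sum_y=(cy, "sum")).reset_index()
    agg[f"cov_{hapW}"] = agg["sum_w"] / agg["n"] / per_copy
    agg[f"cov_{hapY}"] = agg["sum_y"] / agg["n"] / per_copy
    agg["cov_total"] = agg[f"cov_{hapW}"] + agg[f"cov_{hapY}"]
    agg["start"] = agg["win"] * window + 1
    agg["end"] = (agg["win"] + 1) * window
    windows = agg[["chrom", "start", "end", f"cov_{hapW}", f"cov_{hapY}", "cov_total"]]

    means = windows.groupby("chrom", observed=True)[
        [f"cov_{hapW}", f"cov_{hapY}", "cov_total"]].mean().reset_index()

    def _call(t):
        k = int(round(t))
        return {1: "monosomic", 2: "disomic", 3: "trisomic"}.get(k, "segmental")

    means["call"] = means["cov_total"].map(_call)
    return CopyNumberProfile(windows=windows, chrom_means=means, window_size=window,
                             haplotypes=tuple(haplotypes))


# ---------------------------------------------------------------------------
# UPD

def detect_upd(events, profile: CopyNumberProfile,
               copy_band=(1.6, 2.4), monosomy_band=(0.6, 1.4),
               absent_max: float = 0.25) -> list:
    """Whole-chromosome homozygosity at total copy two is uniparental disomy.

    A chromosome whose mean coverage for one haplotype is near zero has
    lost that homolog everywhere; at total copy ~2 the remaining homolog
    was duplicated (UPD), at total copy ~1 nothing replaced it (monosomy,
    not UPD).  Whole-chromosome LOH events from the caller corroborate
    the calls (the retained haplotype is cross-checked) but coverage is
    authoritative, since a monosomic chromosome yields no classifiable
    LOH tract at all.
    """
    hapW, hapY = profile.haplotypes
    whole_events = {ev.chrom: ev for ev in events
                    if getattr(ev, "whole_chromosome", False)}
    calls = []
    for _, row in profile.chrom_means.iterrows():
        chrom = row["chrom"]
        cov = {hapW: float(row[f"cov_{hapW}"]), hapY: float(row[f"cov_{hapY}"])}
        lost = min(cov, key=cov.get)
        if cov[lost] > absent_max:
            continue
        retained = hapY if lost == hapW else hapW
        total = float(row["cov_total"])
        ev = whole_events.get(chrom)
        note = f"retained={retained};cov_total={total:.2f}"
        if ev is not None and ev.retained != retained:
            note += f";caller_retained={ev.retained}"
        if ev is not None:
            span = (ev.start_pos, ev.end_pos)
        else:
            wins = profile.windows[profile.windows["chrom"] == chrom]
            span = (int(wins["start"].min()), int(wins["end"].max()))
        size = span[1] - span[0] + 1
        if copy_band[0] <= total <= copy_band[1]:
            calls.append(StructuralCall(kind="UPD", chrom=chrom, start=span[0],
                                        end=span[1], size=size, haplotype=lost,
                                        note=note))
        elif monosomy_band[0] <= total <= monosomy_band[1]:
            calls.append(StructuralCall(kind="monosomy", chrom=chrom, start=span[0],
                                        end=span[1], size=size, haplotype=lost,
                                        note=note))
    return calls


# ---------------------------------------------------------------------------
# large CNVs

def detect_large_cnv(profile: CopyNumberProfile, min_size: int = 5000,
                     del_hap_max: float = 0.25, dup_hap_min: float = 1.6,
                     del_total_max: float = 1.6, dup_total_min: float = 2.4) -> list:
    """Merge runs of windows with lost or doubled haplotype coverage.

    A deletion requires the haplotype coverage near zero *and* the total
    below ``del_total_max`` (so plain LOH at copy two is not called); a
    duplication requires the haplotype near two and the total above
    ``dup_total_min``.  Runs shorter than ``min_size`` are discarded;
    calls reaching an end of the covered chromosome span are flagged
    terminal.
    """
    hapW, hapY = profile.haplotypes
    calls = []
    for chrom, grp in profile.windows.groupby("chrom", observed=True):
        grp = grp.sort_values("start").reset_index(drop=True)
        first_start = int(grp["start"].iloc[0])
        last_end = int(grp["end"].iloc[-1])
        for hap in (hapW, hapY):
            cov = grp[f"cov_{hap}"].to_numpy()
            tot = grp["cov_total"].to_numpy()
            for kind, mask in (
                ("deletion", (cov <= del_hap_max) & (tot <= del_total_max)),
                ("duplication", (cov >= dup_hap_min) & (tot >= dup_total_min)),
            ):
                runs = _true_runs(mask)
                for s, e in runs:
                    start = int(grp["start"].iloc[s])
                    end = int(grp["end"].iloc[e])
                    size = end - start + 1
                    if size < min_size:
                        continue
                    terminal = start == first_start or end == last_end
                    calls.append(StructuralCall(
                        kind=("terminal " if terminal else "interstitial ") + kind,
                        chrom=chrom, start=start, end=end, size=size, haplotype=hap))
    return calls


def _true_runs(mask: np.ndarray):
    runs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


# ---------------------------------------------------------------------------
# translocation prediction

def predict_translocation(deletion: StructuralCall, duplication: StructuralCall,
                          elements: pd.DataFrame, centromeres: dict,
                          chromosome_lengths: dict, tolerance: int = 2000,
                          repeat_classes=("Ty", "delta")) -> StructuralCall:
    """Predict the size of the translocation behind a coupled terminal
    deletion/duplication pair.

    The predicted chromosome consists of the centromere-containing
    portion retained on the deleted chromosome plus the duplicated
    terminal portion of the other chromosome; both breakpoints must lie
    within ``tolerance`` of an annotated dispersed repeat (Ty/delta by
    default), the usual substrates of such rearrangements.
    """
    if deletion.chrom == duplication.chrom:
        raise PredictionError("deletion and duplication must be on different chromosomes")
    if "deletion" not in deletion.kind or "duplication" not in duplication.kind:
        raise PredictionError("calls must be a deletion and a duplication")

    cen_del = centromeres[deletion.chrom]
    len_del = chromosome_lengths[deletion.chrom]
    # breakpoint of a terminal deletion = its non-telomeric edge
    if deletion.start <= 1 or deletion.start < cen_del <= deletion.end:
        del_bp = deletion.end          # deletion covers the left arm end
        retained = len_del - del_bp
    else:
        del_bp = deletion.start
        retained = del_bp

    len_dup = chromosome_lengths[duplication.chrom]
    cen_dup = centromeres[duplication.chrom]
    if duplication.size <= 0:
        dup_bp = duplication.start
        dup_size = 0
    elif duplication.start <= 1 or duplication.end < cen_dup:
        dup_bp = duplication.end
        dup_size = dup_bp
    else:
        dup_bp = duplication.start
        dup_size = len_dup - dup_bp

    names = []
    for chrom, bp, label in ((deletion.chrom, del_bp, "deletion"),
                             (duplication.chrom, dup_bp, "duplication")):
        near = elements[(elements["chrom"] == chrom)
                        & (elements["cls"].isin(repeat_classes))
                        & (elements["start"] - tolerance <= bp)
                        & (elements["end"] + tolerance >= bp)]
        if near.empty:
            raise PredictionError(
                f"no {'/'.join(repeat_classes)} element within {tolerance} bp of the "
                f"{label} breakpoint {chrom}:{bp}")
        row = near.iloc[0]
        names.append(f"{row['cls']}@{chrom}:{int(row['start'])}-{int(row['end'])}")

    size = int(retained + dup_size)
    return StructuralCall(kind="predicted translocation", chrom=deletion.chrom,
                          start=del_bp, end=del_bp, size=size,
                          haplotype=deletion.haplotype,
                          chrom2=duplication.chrom, start2=dup_bp, end2=dup_bp,
                          elements=";".join(names),
                          note=f"retained={int(retained)};duplicated={int(dup_size)}")


# ---------------------------------------------------------------------------
# rDNA repeat counting

@dataclass
class RdnaEstimate:
    total: float
    per_haplotype: dict = field(default_factory=dict)


def rdna_copy_number(rdna_coverage, baseline_coverage,
                     w_counts=None, y_counts=None,
                     haplotypes=("W", "Y")) -> RdnaEstimate:
    """Estimate rDNA repeat numbers from relative sequence coverage.

    Total repeats = 2 x (mean rDNA coverage / mean single-copy coverage);
    when haplotype-specific read counts inside the array are supplied the
    total is split proportionally to the haplotype read fractions, giving
    the repeat number on each homolog separately.
    """
    base = np.asarray(baseline_coverage, dtype=float)
    rd = np.asarray(rdna_coverage, dtype=float)
    if base.size == 0 or base.mean() <= 0:
        raise InputError("single-copy baseline coverage is zero")
    total = 2.0 * rd.mean() / base.mean() if rd.size else 0.0
    est = RdnaEstimate(total=float(total))
    if w_counts is not None and y_counts is not None:
        sw = float(np.sum(w_counts))
        sy = float(np.sum(y_counts))
        hapW, hapY = haplotypes
        if sw + sy > 0:
            est.per_haplotype = {hapW: total * sw / (sw + sy),
                                 hapY: total * sy / (sw + sy)}
        else:
            est.per_haplotype = {hapW: 0.0, hapY: 0.0}
    return est
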