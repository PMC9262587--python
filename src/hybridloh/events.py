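"""Planting genome-instability events and the ground-truth ledger.

Event vocabulary
----------------
``conversion``
    Gene conversion: an interstitial tract on the recipient (lesion-
    carrying) homolog is overwritten by the donor's alleles, producing
    interstitial LOH (I-LOH) flanked by heterozygosity.
``crossover`` / ``bir``
    Reciprocal crossover or break-induced replication: every marker
    distal to the breakpoint (away from the centromere) becomes
    homozygous for the donor haplotype (T-LOH).  The two mechanisms
    leave the same footprint in a single surviving lineage.
``upd``
    Uniparental disomy: one homolog is lost and the other duplicated;
    the whole chromosome is homozygous at total copy number two.
``monosomy`` / ``trisomy``
    Whole-chromosome loss / gain of the target haplotype.
``deletion`` / ``duplication``
    Interstitial copy-number change of the target haplotype over an
    explicit interval or sampled length.
``translocation``
    Coupled terminal deletion on one chromosome and terminal duplication
    on another, with both breakpoints at annotated repeat elements (the
    signature of a non-reciprocal translocation retained in one product).
``snv`` / ``indel``
    De novo point mutation / short deletion carried by one haplotype,
    recorded in the ledger with a planned mutant-read fraction.
``rdna_resize``
    Set the per-haplotype rDNA repeat counts.

Every realized event is written to the truth ledger, which round-trips
losslessly through a versioned TSV and can be replayed onto a fresh
genome to reproduce the modified genome exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._util import rng_from
from .errors import ConfigurationError, PlanningError
from .genome import DiploidGenome

LEDGER_HEADER = "#hybridloh truth-ledger v1\tcoordinates=1-based inclusive"

LEDGER_COLUMNS = [
    "event_id", "kind", "loh_type", "cls", "chrom", "start", "end",
    "breakpoint", "target", "retained", "chrom2", "start2", "end2",
    "ref", "alt", "fraction", "n_snps", "note",
]

SUBSTITUTION_CLASSES = (
    "C:G>T:A", "C:G>A:T", "C:G>G:C", "T:A>C:G", "T:A>A:T", "T:A>G:C",
)


@dataclass
class PlannedEvent:
    """One requested event; unset coordinates are sampled at apply time.

    ``target`` is the affected haplotype: the one that loses alleles for
    conversion/crossover/BIR/UPD/monosomy/deletion, the one gained for
    trisomy/duplication, and the mutation carrier for snv/indel.
    """

    kind: str
    target: str = "W"
    chrom: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    length: Optional[int] = None
    crossover_associated: bool = False
    arm: Optional[str] = None            # 'L' or 'R' for terminal events
    partner_chrom: Optional[str] = None  # translocation duplication side
    partner_pos: Optional[int] = None
    ref: Optional[str] = None
    alt: Optional[str] = None
    fraction: Optional[float] = None
    rdna_repeats: Optional[dict] = None


@dataclass
class EventPlan:
    """A batch of planned events plus the sampling distributions they share.

    Tract lengths for conversions are lognormal with the configured
    medians (10 kb for crossover-associated tracts, 3 kb otherwise) and
    shape ``tract_sigma``; positions are uniform per bp unless pinned.
    """

    events: list = field(default_factory=list)
    tract_median_co: float = 10_000.0
    tract_median_noco: float = 3_000.0
    tract_sigma: float = 0.9
    min_snps: int = 2
    min_separation: int = 20_000
    snv_class_weights: dict = field(
        default_factory=lambda: {c: 1.0 / 6.0 for c in SUBSTITUTION_CLASSES}
    )
    snv_fraction: float = 0.5
    indel_fraction: float = 0.5

    def __post_init__(self):
        total = sum(self.snv_class_weights.values())
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ConfigurationError("substitution-class weights must sum to 1")
        if self.tract_median_co <= 0 or self.tract_median_noco <= 0:
            raise ConfigurationError("tract medians must be positive")


def _other(genome: DiploidGenome, hap: str) -> str:
    a, b = genome.config.haplotypes
    if hap == a:
        return b
    if hap == b:
        return a
    raise PlanningError(f"unknown haplotype {hap!r}")


class _Occupancy:
    """Per-chromosome record of event footprints, enforcing separation."""

    def __init__(self, min_separation: int):
        self.sep = min_separation
        self.by_chrom: dict = {}

    def free(self, chrom: str, start: int, end: int) -> bool:
        for a, b in self.by_chrom.get(chrom, []):
            if start <= b + self.sep and end >= a - self.sep:
                return False
        return True

    def chrom_free(self, chrom: str) -> bool:
        return not self.by_chrom.get(chrom, [])

    def claim(self, chrom: str, start: int, end: int) -> None:
        self.by_chrom.setdefault(chrom, []).append((int(start), int(end)))


def _sample_chrom(rng, config) -> str:
    names = config.chromosomes
    lengths = np.array([config.chromosome_lengths[c] for c in names], dtype=float)
    return names[rng.choice(len(names), p=lengths / lengths.sum())]


def _snp_mask(snps: pd.DataFrame, chrom: str, start: int, end: int) -> np.ndarray:
    return ((snps["chrom"] == chrom) & (snps["pos"] >= start) & (snps["pos"] <= end)).to_numpy()


def apply_events(genome: DiploidGenome, plan: EventPlan, seed=None,
                 elements: Optional[pd.DataFrame] = None,
                 repeat_classes=("Ty", "delta"),
                 repeat_tolerance: int = 2000):
    """Realize a plan on a copy of ``genome``; return (genome, truth ledger).

    Unpinned coordinates are sampled (uniform per bp for positions,
    lognormal for conversion tracts); sampled footprints are rejected if
    they fall within ``plan.min_separation`` of an earlier event on the
    same chromosome, or if a conversion tract would cover fewer than
    ``plan.min_snps`` markers.  An empty plan returns an unchanged genome
    and an empty ledger.
    """
    rng = rng_from(seed)
    out = genome.copy()
    cfg = out.config
    hapW, hapY = cfg.haplotypes
    snps = out.snps
    occ = _Occupancy(plan.min_separation)
    rows = []

    def record(**kw):
        row = {c: kw.get(c, "") for c in LEDGER_COLUMNS}
        row["event_id"] = len(rows) + 1
        rows.append(row)

    def homozygose(mask: np.ndarray, lost: str) -> None:
        kept = _other(out, lost)
        total = snps.loc[mask, f"n_{lost}"] + snps.loc[mask, f"n_{kept}"]
        snps.loc[mask, f"n_{kept}"] = total
        snps.loc[mask, f"n_{lost}"] = 0

    for ev in plan.events:
        kind = ev.kind
        target = ev.target
        if target not in cfg.haplotypes:
            raise PlanningError(f"haplotype {target!r} not in genome")
        retained = _other(out, target)

        if kind == "conversion":
            median = plan.tract_median_co if ev.crossover_associated else plan.tract_median_noco
            for _ in range(200):
                chrom = ev.chrom or _sample_chrom(rng, cfg)
                clen = cfg.chromosome_lengths[chrom]
                if ev.start is not None and ev.end is not None:
                    start, end = ev.start, ev.end
                else:
                    tract = ev.length or max(1, int(rng.lognormal(math.log(median), plan.tract_sigma)))
                    start = int(rng.integers(1, max(2, clen - tract)))
                    end = min(start + tract - 1, clen)
                mask = _snp_mask(snps, chrom, start, end)
                pinned = ev.start is not None
                if (mask.sum() >= plan.min_snps or pinned) and (occ.free(chrom, start, end) or pinned):
                    break
            else:
                raise PlanningError("could not place conversion tract after 200 attempts")
            homozygose(mask, target)
            occ.claim(chrom, start, end)
            record(kind=kind, loh_type="I-LOH", cls="CON", chrom=chrom, start=start,
                   end=end, breakpoint=start, target=target, retained=retained,
                   n_snps=int(mask.sum()))

        elif kind in ("crossover", "bir"):
            for _ in range(200):
                chrom = ev.chrom or _sample_chrom(rng, cfg)
                clen = cfg.chromosome_lengths[chrom]
                cen = cfg.centromeres[chrom]
                bp = ev.start if ev.start is not None else int(rng.integers(1, clen + 1))
                if ev.arm == "L" or (ev.arm is None and bp < cen):
                    start, end = 1, bp
                else:
                    start, end = bp, clen
                mask = _snp_mask(snps, chrom, start, end)
                pinned = ev.start is not None
                if (mask.sum() >= plan.min_snps or pinned) and (occ.free(chrom, start, end) or pinned):
                    break
            else:
                raise PlanningError("could not place terminal event after 200 attempts")
            homozygose(mask, target)
            occ.claim(chrom, start, end)
            record(kind=kind, loh_type="T-LOH", cls="CO/BIR", chrom=chrom, start=start,
                   end=end, breakpoint=bp, target=target, retained=retained,
                   n_snps=int(mask.sum()))

        elif kind in ("upd", "monosomy", "trisomy"):
            for _ in range(200):
                chrom = ev.chrom or _sample_chrom(rng, cfg)
                if occ.chrom_free(chrom) or ev.chrom is not None:
                    break
            else:
                raise PlanningError("no free chromosome for whole-chromosome event")
            clen = cfg.chromosome_lengths[chrom]
            mask = (snps["chrom"] == chrom).to_numpy()
            if kind == "upd":
                snps.loc[mask, f"n_{target}"] = 0
                snps.loc[mask, f"n_{retained}"] = 2
            elif kind == "monosomy":
                snps.loc[mask, f"n_{target}"] = 0
            else:  # trisomy gains the target haplotype
                snps.loc[mask, f"n_{target}"] = 2
            occ.claim(chrom, 1, clen)
            record(kind=kind, loh_type="T-LOH" if kind == "upd" else "",
                   cls="UPD" if kind == "upd" else kind,
                   chrom=chrom, start=1, end=clen, target=target,
                   retained=retained if kind != "trisomy" else target,
                   n_snps=int(mask.sum()))

        elif kind in ("deletion", "duplication"):
            if ev.length is None and (ev.start is None or ev.end is None):
                raise PlanningError(f"{kind} requires an explicit length or interval")
            for _ in range(200):
                chrom = ev.chrom or _sample_chrom(rng, cfg)
                clen = cfg.chromosome_lengths[chrom]
                if ev.start is not None and ev.end is not None:
                    start, end = ev.start, ev.end
                else:
                    start = int(rng.integers(1, max(2, clen - ev.length)))
                    end = min(start + ev.length - 1, clen)
                pinned = ev.start is not None
                if occ.free(chrom, start, end) or pinned:
                    break
            else:
                raise PlanningError("could not place CNV after 200 attempts")
            mask = _snp_mask(snps, chrom, start, end)
            snps.loc[mask, f"n_{target}"] = 0 if kind == "deletion" else 2
            occ.claim(chrom, start, end)
            record(kind=kind, chrom=chrom, start=start, end=end, target=target,
                   retained=retained if kind == "deletion" else target,
                   n_snps=int(mask.sum()))

        elif kind == "translocation":
            fully_pinned = ev.start is not None and ev.partner_pos is not None
            if elements is None and not fully_pinned:
                raise PlanningError("translocation requires an element annotation")
            del_chrom = ev.chrom or _sample_chrom(rng, cfg)
            dup_chrom = ev.partner_chrom or _sample_chrom(rng, cfg)
            if del_chrom == dup_chrom:
                raise PlanningError("translocation needs two distinct chromosomes")
            if elements is None:
                bp1, bp2 = int(ev.start), int(ev.partner_pos)
            else:
                bp1 = _element_breakpoint(elements, del_chrom, ev.start, repeat_classes,
                                          repeat_tolerance, cfg, rng)
                bp2 = _element_breakpoint(elements, dup_chrom, ev.partner_pos,
                                          repeat_classes, repeat_tolerance, cfg, rng)
            # terminal deletion distal of bp1; terminal duplication distal of bp2
            s1, e1 = _distal_span(cfg, del_chrom, bp1)
            s2, e2 = _distal_span(cfg, dup_chrom, bp2)
            m1 = _snp_mask(snps, del_chrom, s1, e1)
            m2 = _snp_mask(snps, dup_chrom, s2, e2)
            snps.loc[m1, f"n_{target}"] = 0
            snps.loc[m2, f"n_{target}"] = 2
            occ.claim(del_chrom, s1, e1)
            occ.claim(dup_chrom, s2, e2)
            record(kind=kind, chrom=del_chrom, start=s1, end=e1, breakpoint=bp1,
                   target=target, retained=retained, chrom2=dup_chrom,
                   start2=s2, end2=e2, n_snps=int(m1.sum() + m2.sum()),
                   note=f"dup_breakpoint={bp2}")

        elif kind == "snv":
            chrom = ev.chrom or _sample_chrom(rng, cfg)
            pos = ev.start if ev.start is not None else int(
                rng.integers(1, cfg.chromosome_lengths[chrom] + 1))
            if ev.ref is not None and ev.alt is not None:
                ref, alt = ev.ref, ev.alt
            else:
                ref, alt = _sample_substitution(rng, plan.snv_class_weights)
            frac = ev.fraction if ev.fraction is not None else plan.snv_fraction
            record(kind=kind, chrom=chrom, start=pos, end=pos, target=target,
                   ref=ref, alt=alt, fraction=frac)

        elif kind == "indel":
            chrom = ev.chrom or _sample_chrom(rng, cfg)
            pos = ev.start if ev.start is not None else int(
                rng.integers(1, cfg.chromosome_lengths[chrom] + 1))
            if ev.ref is not None:
                ref, alt = ev.ref, ev.alt or ""
            else:
                n = int(rng.integers(1, 4))  # paper-scale: most in/dels delete 1-3 bp
                ref = "".join(rng.choice(list("ACGT"), size=n))
                alt = ""
            frac = ev.fraction if ev.fraction is not None else plan.indel_fraction
            record(kind=kind, chrom=chrom, start=pos, end=pos + max(0, len(ref) - 1),
                   target=target, ref=ref, alt=alt, fraction=frac)

        elif kind == "rdna_resize":
            if not ev.rdna_repeats:
                raise PlanningError("rdna_resize requires repeat counts")
            out.rdna_repeats.update({k: int(v) for k, v in ev.rdna_repeats.items()})
            rd = cfg.rdna
            record(kind=kind, chrom=rd.chrom if rd else "", start=rd.start if rd else "",
                   end=rd.end if rd else "",
                   note=";".join(f"{k}={v}" for k, v in sorted(ev.rdna_repeats.items())))

        else:
            raise PlanningError(f"unknown event kind {kind!r}")

    ledger = pd.DataFrame(rows, columns=LEDGER_COLUMNS)
    return out, ledger


def _distal_span(cfg, chrom, bp):
    """Span from breakpoint to the telomere on the arm not holding the centromere."""
    cen = cfg.centromeres[chrom]
    clen = cfg.chromosome_lengths[chrom]
    if bp >= cen:
        return bp, clen
    return 1, bp


def _element_breakpoint(elements, chrom, pinned, repeat_classes, tolerance, cfg, rng):
    """Pick (or verify) a breakpoint at a repeat element on ``chrom``."""
    cand = elements[(elements["chrom"] == chrom) & (elements["cls"].isin(repeat_classes))]
    if pinned is not None:
        near = cand[(cand["start"] - tolerance <= pinned) & (cand["end"] + tolerance >= pinned)]
        if near.empty:
            raise PlanningError(
                f"no {'/'.join(repeat_classes)} element within {tolerance} bp of "
                f"{chrom}:{pinned}")
        return int(pinned)
    cen = cfg.centromeres[chrom]
    # avoid breakpoints on top of the centromere so the deletion stays terminal
    cand = cand[(cand["end"] < cen - tolerance) | (cand["start"] > cen + tolerance)]
    if cand.empty:
        raise PlanningError(f"no compatible repeat element on {chrom}")
    row = cand.iloc[int(rng.integers(0, len(cand)))]
    return int((row["start"] + row["end"]) // 2)


def _sample_substitution(rng, weights):
    classes = list(weights)
    probs = np.array([weights[c] for c in classes], dtype=float)
    cls = classes[rng.choice(len(classes), p=probs / probs.sum())]
    pyr_ref, pyr_alt = cls.split(">")[0].split(":")[0], cls.split(">")[1].split(":")[0]
    if rng.integers(0, 2):
        return pyr_ref, pyr_alt
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return comp[pyr_ref], comp[pyr_alt]


# ---------------------------------------------------------------------------
# ledger I/O and replay

def write_ledger(ledger: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(LEDGER_HEADER + "\n")
        ledger.to_csv(fh, sep="\t", index=False)


def read_ledger(path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#hybridloh truth-ledger"):
            raise ConfigurationError("not a hybridloh truth ledger (missing header)")
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    for col in ("event_id", "start", "end", "breakpoint", "start2", "end2", "n_snps"):
        df[col] = df[col].map(lambda v: int(float(v)) if v != "" else "")
    df["fraction"] = df["fraction"].map(lambda v: float(v) if v != "" else "")
    return df[LEDGER_COLUMNS]


def plan_from_ledger(ledger: pd.DataFrame) -> EventPlan:
    """Rebuild a fully pinned plan from a truth ledger (for replay)."""
    events = []
    for _, row in ledger.iterrows():
        kind = row["kind"]
        ev = PlannedEvent(kind=kind, target=row["target"] or "W",
                          chrom=row["chrom"] or None)
        if kind in ("conversion", "deletion", "duplication", "snv", "indel"):
            ev.start, ev.end = int(row["start"]), int(row["end"])
            if kind in ("snv", "indel"):
                ev.ref, ev.alt = row["ref"], row["alt"]
                ev.fraction = float(row["fraction"]) if row["fraction"] != "" else None
        elif kind in ("crossover", "bir"):
            bp = int(row["breakpoint"])
            ev.start = bp
            ev.arm = "L" if int(row["start"]) == 1 and int(row["end"]) == bp else "R"
        elif kind == "translocation":
            ev.start = int(row["breakpoint"])
            ev.partner_chrom = row["chrom2"]
            note = dict(kv.split("=") for kv in row["note"].split(";") if "=" in kv)
            ev.partner_pos = int(note["dup_breakpoint"])
        elif kind == "rdna_resize":
            ev.rdna_repeats = {k: int(v) for k, v in
                               (kv.split("=") for kv in row["note"].split(";") if "=" in kv)}
        events.append(ev)
    return EventPlan(events=events, min_snps=0, min_separation=0)


def replay_ledger(genome: DiploidGenome, ledger: pd.DataFrame,
                  elements: Optional[pd.DataFrame] = None) -> DiploidGenome:
    """Re-apply a truth ledger to a fresh genome; reproduces the modified genome."""
    plan = plan_from_ledger(ledger)
    replayed, _ = apply_events(genome, plan, seed=0, elements=elements,
                               repeat_tolerance=10**9)
    return replayed
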