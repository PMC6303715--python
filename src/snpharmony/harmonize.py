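"""Cross-dataset SNP panel harmonization.

Independently genotyped SNP panels disagree in three ways this module
repairs or audits:

1. **Panel overlap** — only loci shared by every dataset are usable;
   unambiguous loci whose allele pairs differ by reverse complement are
   auto-reconciled, irreconcilable pairs are quarantined.
2. **Strand designation** — A/T and C/G polymorphisms equal their own
   reverse complement, so a dataset genotyped off the opposite strand
   silently swaps the allele labels.  Using geographic replicate sample
   pairs (the same population sampled by two datasets), the mismatch rate of
   *unambiguous* loci is measured on a cumulative minor-allele-frequency
   grid (0.05 steps up to 0.45); the largest grid value keeping mean
   confidence at or above the requirement (default 0.95), and above it at
   every locale, becomes the MAF threshold.  Ambiguous loci are then kept,
   flipped, or discarded by comparing replicate frequencies against that
   threshold, requiring a consistent consensus across locales.
3. **Locus quality** — tiered filters: within-location missingness rules,
   Hardy–Weinberg exact tests with joint FDR correction, and a replicate
   upper-5% F_ST screen.  Every decision lands in a :class:`QCLedger`.

The default stage order runs the replicate-F_ST screen *after* strand
resolution: a strand-flipped locus shows an enormous replicate F_ST, so
screening first would discard exactly the loci the correction rescues.  Set
``fst_screen_before_strand`` to restore the narrative order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import (
    COMPLEMENT,
    MISSING,
    DistanceMatrix,
    GenotypePanel,
    LocusDef,
    PanelError,
    merge_panels,
)
from .popgen import bh_fdr, hwe_exact_test, upper_quantile_loci, wc_components

logger = logging.getLogger(__name__)

__all__ = [
    "ReplicatePair",
    "StrandCalibration",
    "StrandResolution",
    "QCLedger",
    "HarmonizationConfig",
    "HarmonizationResult",
    "intersect_panels",
    "is_ambiguous",
    "allele_frequency",
    "calibrate_strand_threshold",
    "resolve_ambiguous_strands",
    "filter_missingness",
    "hwe_filter",
    "replicate_fst_screen",
    "run_harmonization",
    "MAF_GRID",
]

#: Cumulative MAF grid (interval right endpoints) used for calibration.
MAF_GRID: tuple[float, ...] = tuple(round(0.05 * k, 2) for k in range(1, 10))

RETAINED = "RETAINED"
DISCARDED = "DISCARDED"

# Verdicts / decisions
MATCHED = "MATCHED"
FLIPPED = "FLIPPED"
INCONCLUSIVE = "INCONCLUSIVE"
KEEP_AS_IS = "KEEP_AS_IS"
FLIP = "FLIP"
DISCARD = "DISCARD"


class CalibrationError(PanelError):
    """Strand calibration could not be computed."""


@dataclass(frozen=True)
class ReplicatePair:
    """The same population sampled independently by two datasets."""

    locale_name: str
    sample_ref: tuple[str, str]  # (location_code, dataset), reference dataset
    sample_alt: tuple[str, str]

    def __post_init__(self) -> None:
        if self.sample_ref[1] == self.sample_alt[1]:
            raise PanelError(
                f"replicate pair {self.locale_name!r}: datasets must differ"
            )


@dataclass
class StrandCalibration:
    """Mismatch error rates of unambiguous loci on the cumulative MAF grid."""

    grid: tuple[float, ...]
    error_rate: dict[str, np.ndarray]      # locale -> per-grid error rate
    bin_counts: dict[str, np.ndarray]      # locale -> cumulative locus counts
    confidence_requirement: float
    selected_threshold: float | None

    def confidence(self, locale: str) -> np.ndarray:
        return 1.0 - self.error_rate[locale]

    @property
    def mean_confidence(self) -> np.ndarray:
        return 1.0 - np.mean([e for e in self.error_rate.values()], axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for locale, err in self.error_rate.items():
            for g, e, n in zip(self.grid, err, self.bin_counts[locale]):
                rows.append(
                    {"locale": locale, "maf_interval": g, "n_loci": int(n),
                     "error_rate": e, "confidence": 1.0 - e}
                )
        for g, mc in zip(self.grid, self.mean_confidence):
            rows.append(
                {"locale": "MEAN", "maf_interval": g, "n_loci": -1,
                 "error_rate": 1.0 - mc, "confidence": mc}
            )
        return pd.DataFrame(rows)


@dataclass
class LocusStrandDecision:
    locus_id: str
    verdicts: dict[str, str]               # locale -> MATCHED/FLIPPED/INCONCLUSIVE
    final: str                             # KEEP_AS_IS / FLIP / DISCARD
    datasets_to_flip: frozenset[str] = frozenset()


@dataclass
class StrandResolution:
    """Per-ambiguous-locus strand verdicts and final decisions."""

    threshold: float
    decisions: dict[str, LocusStrandDecision] = field(default_factory=dict)

    def final(self, locus_id: str) -> str:
        return self.decisions[locus_id].final

    def counts(self) -> dict[str, int]:
        out = {KEEP_AS_IS: 0, FLIP: 0, DISCARD: 0}
        for d in self.decisions.values():
            out[d.final] += 1
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.decisions.values():
            rows.append(
                {
                    "locus_id": d.locus_id,
                    "final": d.final,
                    "datasets_to_flip": ",".join(sorted(d.datasets_to_flip)),
                    **{f"verdict[{k}]": v for k, v in sorted(d.verdicts.items())},
                }
            )
        return pd.DataFrame(rows)


@dataclass
class QCLedger:
    """Per-locus audit trail: every filter decision, one final status."""

    entries: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)
    status: dict[str, str] = field(default_factory=dict)

    def record(self, locus_id: str, rule_id: str, outcome: str, detail: str = "") -> None:
        self.entries.setdefault(locus_id, []).append((rule_id, outcome, detail))

    def discard(self, locus_id: str, rule_id: str, detail: str = "") -> None:
        self.record(locus_id, rule_id, "FAIL", detail)
        self.status[locus_id] = DISCARDED

    def retain(self, locus_id: str) -> None:
        self.status.setdefault(locus_id, RETAINED)

    def is_discarded(self, locus_id: str) -> bool:
        return self.status.get(locus_id) == DISCARDED

    def loci_with_status(self, status: str) -> list[str]:
        return [l for l, s in self.status.items() if s == status]

    def counts_by_rule(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lid, recs in self.entries.items():
            if self.status.get(lid) != DISCARDED:
                continue
            for rule, outcome, _ in recs:
                if outcome == "FAIL":
                    out[rule] = out.get(rule, 0) + 1
                    break  # first failing rule is the recorded cause
        return out

    def validate(self) -> None:
        for lid, s in self.status.items():
            if s == DISCARDED:
                fails = [r for r in self.entries.get(lid, []) if r[1] == "FAIL"]
                if not fails:
                    raise PanelError(f"ledger: {lid} discarded without a failing rule")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lid in sorted(self.status):
            recs = self.entries.get(lid, [])
            if not recs:
                rows.append({"locus_id": lid, "rule_id": "", "outcome": "",
                             "detail": "", "final_status": self.status[lid]})
            for rule, outcome, detail in recs:
                rows.append({"locus_id": lid, "rule_id": rule, "outcome": outcome,
                             "detail": detail, "final_status": self.status[lid]})
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ------------------------------------------------------------------- intersect
def is_ambiguous(locus: LocusDef) -> bool:
    """True iff the locus is an A/T or C/G polymorphism."""
    return locus.is_ambiguous


def intersect_panels(
    panels: Sequence[GenotypePanel],
) -> tuple[list[str], dict[int, list[str]], list[str], list[GenotypePanel]]:
    """Shared loci across panels, with allele-designation alignment.

    Returns ``(shared_ids, private_by_panel, conflicts, aligned_panels)``.
    ``aligned_panels`` are copies in which every shared locus carries the
    reference (first) panel's allele pair and designation; dosages are
    recoded g -> 2 - g wherever the designation swapped.  Unambiguous loci
    whose pairs differ by reverse complement are reconciled; irreconcilable
    pairs land in ``conflicts`` and are excluded from ``shared_ids``.
    """
    if len(panels) < 2:
        raise PanelError("intersection needs at least two panels")
    id_sets = [set(p.locus_ids) for p in panels]
    shared = set.intersection(*id_sets)
    private = {
        i: sorted(id_sets[i] - shared) for i in range(len(panels))
    }
    aligned = [panels[0].copy()] + [p.copy() for p in panels[1:]]
    ref = aligned[0]
    conflicts: list[str] = []
    shared_ordered = [lid for lid in ref.locus_ids if lid in shared]

    for lid in list(shared_ordered):
        ref_pair = ref.locus(lid).allele_pair
        ref_set = frozenset(ref_pair)
        comp_pair = (COMPLEMENT[ref_pair[0]], COMPLEMENT[ref_pair[1]])
        for p in aligned[1:]:
            pair = p.locus(lid).allele_pair
            pset = frozenset(pair)
            if pset == ref_set:
                if pair != ref_pair:
                    p.swap_designation(lid)
            elif pset == frozenset(comp_pair):
                # Same locus read on the opposite strand; relabel alleles,
                # recoding dosages only if the designation swaps too.
                j = p.locus_index(lid)
                if pair == comp_pair:
                    p.loci[j] = LocusDef(
                        lid, ref_pair, p.loci[j].linkage_group, p.loci[j].source_panels
                    )
                else:
                    p.swap_designation(lid)
                    j = p.locus_index(lid)
                    p.loci[j] = LocusDef(
                        lid, ref_pair, p.loci[j].linkage_group, p.loci[j].source_panels
                    )
            else:
                conflicts.append(lid)
                break
    conflicts = sorted(set(conflicts))
    shared_ordered = [lid for lid in shared_ordered if lid not in set(conflicts)]
    if not shared_ordered:
        raise PanelError("no shared loci across panels; nothing to synthesize")
    return shared_ordered, private, conflicts, aligned


def allele_frequency(
    panel: GenotypePanel, location_code: str, locus_id: str
) -> tuple[float, int]:
    """Designated-allele frequency among non-missing calls, plus call count."""
    return panel.allele_frequency(location_code, locus_id)


def _panel_for_sample(
    panels: Sequence[GenotypePanel], sample: tuple[str, str]
) -> GenotypePanel:
    loc, ds = sample
    for p in panels:
        for s in p.samples:
            if s.location_code == loc and s.dataset == ds:
                return p
    raise PanelError(f"sample {sample!r} not found in any panel")


# ------------------------------------------------------------------ calibration
def calibrate_strand_threshold(
    pairs: Sequence[ReplicatePair],
    panels: Sequence[GenotypePanel],
    unambiguous_loci: Sequence[str],
    confidence_requirement: float = 0.95,
    grid: Sequence[float] = MAF_GRID,
) -> StrandCalibration:
    """Error/confidence calibration of cross-dataset frequency agreement.

    For each locale, unambiguous loci are folded to MAF orientation in the
    reference dataset and binned cumulatively by reference MAF <= x for each
    grid value x; the error rate at x is the fraction of binned loci whose
    alternate-dataset frequency of the same (folded) allele exceeds 0.5.
    Confidences (1 - error) are averaged across locales; the selected
    threshold is the largest grid value whose mean confidence meets the
    requirement and whose per-locale confidence strictly exceeds it
    everywhere, or None when no grid value qualifies.

    An empty bin contributes error 0 (vacuous confidence); calibration fails
    only if every locale has empty bins at every grid value.
    """
    if not pairs:
        raise CalibrationError("at least one replicate pair required")
    grid = tuple(grid)
    error_rate: dict[str, np.ndarray] = {}
    bin_counts: dict[str, np.ndarray] = {}
    any_bin = False
    for pair in pairs:
        ref_panel = _panel_for_sample(panels, pair.sample_ref)
        alt_panel = _panel_for_sample(panels, pair.sample_alt)
        mafs: list[float] = []
        mismatches: list[bool] = []
        for lid in unambiguous_loci:
            f_ref, n_ref = ref_panel.allele_frequency(pair.sample_ref[0], lid)
            f_alt, n_alt = alt_panel.allele_frequency(pair.sample_alt[0], lid)
            if n_ref == 0 or n_alt == 0:
                continue
            if f_ref > 0.5:  # fold to MAF orientation of the reference dataset
                f_ref, f_alt = 1.0 - f_ref, 1.0 - f_alt
            mafs.append(f_ref)
            mismatches.append(f_alt > 0.5)
        maf_arr = np.asarray(mafs)
        mis_arr = np.asarray(mismatches, dtype=bool)
        errs = np.zeros(len(grid))
        counts = np.zeros(len(grid), dtype=int)
        for gi, x in enumerate(grid):
            sel = maf_arr <= x + 1e-12
            counts[gi] = int(sel.sum())
            if counts[gi] > 0:
                errs[gi] = float(mis_arr[sel].mean())
                any_bin = True
        error_rate[pair.locale_name] = errs
        bin_counts[pair.locale_name] = counts
    if not any_bin:
        raise CalibrationError("empty calibration bins at every grid value")

    mean_conf = 1.0 - np.mean([e for e in error_rate.values()], axis=0)
    selected: float | None = None
    for gi in range(len(grid) - 1, -1, -1):
        if mean_conf[gi] >= confidence_requirement and all(
            1.0 - error_rate[loc][gi] > confidence_requirement for loc in error_rate
        ):
            selected = grid[gi]
            break
    return StrandCalibration(
        grid=grid,
        error_rate=error_rate,
        bin_counts=bin_counts,
        confidence_requirement=confidence_requirement,
        selected_threshold=selected,
    )


# ------------------------------------------------------------------- resolution
def _verdict(f_ref: float, f_alt: float, t: float) -> str:
    if np.isnan(f_ref) or np.isnan(f_alt):
        return INCONCLUSIVE
    lo, hi = t, 1.0 - t
    ref_low, ref_high = f_ref < lo, f_ref > hi
    alt_low, alt_high = f_alt < lo, f_alt > hi
    if (ref_low and alt_low) or (ref_high and alt_high):
        return MATCHED
    if (ref_low and alt_high) or (ref_high and alt_low):
        return FLIPPED
    return INCONCLUSIVE


def resolve_ambiguous_strands(
    pairs: Sequence[ReplicatePair],
    panels: Sequence[GenotypePanel],
    ambiguous_loci: Sequence[str],
    threshold: float,
    consensus: str = "strict",
) -> StrandResolution:
    """Keep/flip/discard each ambiguous locus from replicate frequencies.

    Per locale, the designated-allele frequency in the reference and
    alternate samples yields MATCHED (both on the same side of the
    [t, 1-t] band), FLIPPED (opposite sides), or INCONCLUSIVE (either
    frequency inside the band, or undefined).  Verdicts are combined per
    alternate *dataset* over that dataset's locales: under the default
    strict consensus a dataset is flipped only when every verdict is
    FLIPPED, trusted only when every verdict is MATCHED, anything else
    discards the locus.  ``consensus='majority'`` relaxes to a majority of
    conclusive verdicts (ties discard).  Datasets with no replicate
    coverage are trusted as-is.
    """
    if threshold is None:
        raise CalibrationError("resolution requires a calibrated threshold")
    datasets = sorted({p.sample_alt[1] for p in pairs})
    res = StrandResolution(threshold=threshold)
    for lid in ambiguous_loci:
        locus = _panel_for_sample(panels, pairs[0].sample_ref).locus(lid)
        if not locus.is_ambiguous:
            raise PanelError(f"locus {lid!r} is not ambiguous")
        verdicts: dict[str, str] = {}
        per_ds: dict[str, list[str]] = {d: [] for d in datasets}
        for pair in pairs:
            ref_panel = _panel_for_sample(panels, pair.sample_ref)
            alt_panel = _panel_for_sample(panels, pair.sample_alt)
            f_ref, n_ref = ref_panel.allele_frequency(pair.sample_ref[0], lid)
            f_alt, n_alt = alt_panel.allele_frequency(pair.sample_alt[0], lid)
            v = _verdict(
                f_ref if n_ref else float("nan"),
                f_alt if n_alt else float("nan"),
                threshold,
            )
            verdicts[pair.locale_name] = v
            per_ds[pair.sample_alt[1]].append(v)

        ds_final: dict[str, str] = {}
        for d, vs in per_ds.items():
            if not vs:
                ds_final[d] = KEEP_AS_IS
                continue
            if consensus == "strict":
                if all(v == FLIPPED for v in vs):
                    ds_final[d] = FLIP
                elif all(v == MATCHED for v in vs):
                    ds_final[d] = KEEP_AS_IS
                else:
                    ds_final[d] = DISCARD
            elif consensus == "majority":
                conclusive = [v for v in vs if v != INCONCLUSIVE]
                n_flip = sum(v == FLIPPED for v in conclusive)
                n_match = len(conclusive) - n_flip
                if not conclusive or n_flip == n_match:
                    ds_final[d] = DISCARD
                else:
                    ds_final[d] = FLIP if n_flip > n_match else KEEP_AS_IS
            else:
                raise ValueError(f"unknown consensus rule {consensus!r}")

        if any(v == DISCARD for v in ds_final.values()):
            final, to_flip = DISCARD, frozenset()
        else:
            to_flip = frozenset(d for d, v in ds_final.items() if v == FLIP)
            final = FLIP if to_flip else KEEP_AS_IS
        res.decisions[lid] = LocusStrandDecision(lid, verdicts, final, to_flip)
    return res


# ---------------------------------------------------------------------- filters
def filter_missingness(
    panel: GenotypePanel,
    ledger: QCLedger,
    call_rate_floor: float = 0.60,
    missing_ceiling: float = 0.15,
    max_bad_samples: int = 5,
) -> None:
    """Two-tier within-location missingness rules.

    Rule A discards a locus whose call rate is <= ``call_rate_floor`` in at
    least one sampling location; rule B discards a locus whose missing
    fraction is >= ``missing_ceiling`` in more than ``max_bad_samples``
    locations.
    """
    n_loc = len(panel.samples)
    call_rates = np.empty((n_loc, panel.n_loci))
    for si, s in enumerate(panel.samples):
        rows = panel.rows_for(s.location_code)
        sub = panel.dosages[rows, :]
        call_rates[si] = (sub != MISSING).mean(axis=0)
    for j, lid in enumerate(panel.locus_ids):
        if ledger.is_discarded(lid):
            continue
        low = np.nonzero(call_rates[:, j] <= call_rate_floor)[0]
        if low.size > 0:
            locs = ",".join(panel.samples[i].location_code for i in low[:5])
            ledger.discard(
                lid, "MISSINGNESS_A",
                f"call rate <= {call_rate_floor} at {low.size} location(s): {locs}",
            )
            continue
        ledger.record(lid, "MISSINGNESS_A", "PASS")
        bad = int((1.0 - call_rates[:, j] >= missing_ceiling - 1e-12).sum())
        if bad > max_bad_samples:
            ledger.discard(
                lid, "MISSINGNESS_B",
                f"missing >= {missing_ceiling} in {bad} locations (> {max_bad_samples})",
            )
        else:
            ledger.record(lid, "MISSINGNESS_B", "PASS", f"{bad} borderline locations")


def hwe_filter(
    panel: GenotypePanel,
    ledger: QCLedger,
    alpha_q: float = 0.05,
    max_sig_samples: int = 3,
) -> None:
    """Exact HWE tests per (locus, location), FDR-corrected jointly.

    A locus is discarded when its BH-adjusted q-value is <= ``alpha_q`` in
    more than ``max_sig_samples`` locations.  Locations with fewer than two
    called individuals at a locus are skipped and recorded.
    """
    counts = panel.counts_by_location()
    tests: list[tuple[str, str, float]] = []
    skipped: dict[str, int] = {}
    active = [
        (j, lid) for j, lid in enumerate(panel.locus_ids) if not ledger.is_discarded(lid)
    ]
    for loc, (n2, n1, n0) in counts.items():
        for j, lid in active:
            n = int(n2[j] + n1[j] + n0[j])
            if n < 2:
                skipped[lid] = skipped.get(lid, 0) + 1
                continue
            p = hwe_exact_test(int(n2[j]), int(n1[j]), int(n0[j]))
            tests.append((lid, loc, p))
    if tests:
        q = bh_fdr([t[2] for t in tests])
    else:
        q = np.array([])
    sig_count: dict[str, int] = {}
    for (lid, loc, _), qv in zip(tests, q):
        if qv <= alpha_q:
            sig_count[lid] = sig_count.get(lid, 0) + 1
    for j, lid in active:
        n_sig = sig_count.get(lid, 0)
        detail = f"q <= {alpha_q} in {n_sig} locations"
        if lid in skipped:
            detail += f"; {skipped[lid]} locations skipped (n < 2)"
        if n_sig > max_sig_samples:
            ledger.discard(lid, "HWE_MULTI", detail)
        else:
            ledger.record(lid, "HWE_MULTI", "PASS", detail)


def replicate_fst_screen(
    pairs: Sequence[ReplicatePair],
    panel: GenotypePanel,
    ledger: QCLedger,
    quantile: float = 0.95,
    max_pairs_allowed: int = 1,
) -> dict[str, set[str]]:
    """Upper-quantile per-locus F_ST screen between replicate samples.

    For each replicate pair the per-locus Weir–Cockerham theta between its
    two samples is computed; loci at or above the empirical ``quantile`` of
    defined thetas form that pair's outlier set.  A locus is discarded when
    it appears in more than ``max_pairs_allowed`` sets.  Loci with undefined
    theta are excluded from the quantile population.  Returns the per-pair
    outlier sets (for the audit trail).
    """
    counts = panel.counts_by_location()
    active = [lid for lid in panel.locus_ids if not ledger.is_discarded(lid)]
    active_idx = [panel.locus_index(l) for l in active]
    top_sets: dict[str, set[str]] = {}
    for pair in pairs:
        ca = tuple(arr[active_idx] for arr in counts[pair.sample_ref[0]])
        cb = tuple(arr[active_idx] for arr in counts[pair.sample_alt[0]])
        a, b, c = wc_components([ca, cb])
        denom = a + b + c
        defined = np.isfinite(denom) & (denom != 0.0)
        thetas = {
            lid: (float(a[k] / denom[k]) if defined[k] else None)
            for k, lid in enumerate(active)
        }
        n_def = sum(1 for t in thetas.values() if t is not None)
        if n_def < 20:
            warnings.warn(
                f"replicate pair {pair.locale_name!r}: only {n_def} loci with "
                "defined F_ST; upper quantile is unstable",
                stacklevel=2,
            )
        if n_def == 0:
            top_sets[pair.locale_name] = set()
            continue
        top_sets[pair.locale_name] = upper_quantile_loci(thetas, quantile)
    occurrences: dict[str, list[str]] = {}
    for locale, s in top_sets.items():
        for lid in s:
            occurrences.setdefault(lid, []).append(locale)
    for lid in active:
        locales = occurrences.get(lid, [])
        if len(locales) > max_pairs_allowed:
            ledger.discard(
                lid, "REPL_FST",
                f"upper {100 * (1 - quantile):.0f}% in pairs: {','.join(sorted(locales))}",
            )
        else:
            ledger.record(lid, "REPL_FST", "PASS", f"{len(locales)} pair(s)")
    return top_sets


# ------------------------------------------------------------------ orchestration
@dataclass(frozen=True)
class HarmonizationConfig:
    reference_dataset: str | None = None   # default: dataset of the first panel
    confidence_requirement: float = 0.95
    call_rate_floor: float = 0.60
    missing_ceiling: float = 0.15
    max_bad_samples: int = 5
    hwe_alpha_q: float = 0.05
    hwe_max_sig_samples: int = 3
    fst_quantile: float = 0.95
    fst_max_pairs_allowed: int = 1
    consensus: str = "strict"
    fst_screen_before_strand: bool = False


@dataclass
class HarmonizationResult:
    merged_panel: GenotypePanel
    ledger: QCLedger
    calibration: StrandCalibration
    resolution: StrandResolution | None
    summary: dict


def run_harmonization(
    panels: Sequence[GenotypePanel],
    pairs: Sequence[ReplicatePair],
    config: HarmonizationConfig = HarmonizationConfig(),
) -> HarmonizationResult:
    """Full synthesis: intersect, QC filters, strand calibration/correction,
    merge.  Every candidate locus receives exactly one final ledger status."""
    if len(panels) < 2:
        raise PanelError("harmonization needs at least two panels")
    if not pairs:
        raise PanelError("harmonization needs at least one replicate pair")
    if config.reference_dataset is not None:
        order = sorted(
            range(len(panels)),
            key=lambda i: 0 if config.reference_dataset in panels[i].datasets else 1,
        )
        panels = [panels[i] for i in order]

    shared, private, conflicts, aligned = intersect_panels(panels)
    ledger = QCLedger()
    for i, ids in private.items():
        ds = ",".join(aligned[i].datasets)
        for lid in ids:
            ledger.discard(lid, "NOT_SHARED", f"private to panel {i} ({ds})")
    for lid in conflicts:
        ledger.discard(lid, "NOT_SHARED", "irreconcilable allele pairs")
    logger.info(
        "intersection: %d unique loci, %d shared, %d conflicts",
        len(set().union(*(set(p.locus_ids) for p in panels))), len(shared), len(conflicts),
    )

    combined = merge_panels(aligned, shared)
    filter_missingness(
        combined, ledger, config.call_rate_floor, config.missing_ceiling,
        config.max_bad_samples,
    )
    logger.info("missingness filter: %d discarded",
                len([l for l in shared if ledger.is_discarded(l)]))
    hwe_filter(combined, ledger, config.hwe_alpha_q, config.hwe_max_sig_samples)

    if config.fst_screen_before_strand:
        replicate_fst_screen(
            pairs, combined, ledger, config.fst_quantile, config.fst_max_pairs_allowed
        )

    surviving = [l for l in shared if not ledger.is_discarded(l)]
    unamb = [l for l in surviving if not combined.locus(l).is_ambiguous]
    amb = [l for l in surviving if combined.locus(l).is_ambiguous]
    calibration = calibrate_strand_threshold(
        pairs, aligned, unamb, config.confidence_requirement
    )
    logger.info("calibration: selected threshold %s", calibration.selected_threshold)

    resolution: StrandResolution | None = None
    if calibration.selected_threshold is None:
        warnings.warn(
            "no MAF threshold met the confidence requirement; all ambiguous "
            "loci discarded", stacklevel=2,
        )
        for lid in amb:
            ledger.discard(lid, "STRAND_DISCARD", "no calibrated threshold")
    else:
        resolution = resolve_ambiguous_strands(
            pairs, aligned, amb, calibration.selected_threshold, config.consensus
        )
        for lid in amb:
            dec = resolution.decisions[lid]
            if dec.final == DISCARD:
                ledger.discard(
                    lid, "STRAND_DISCARD",
                    "verdicts: " + ",".join(f"{k}={v}" for k, v in sorted(dec.verdicts.items())),
                )
            else:
                ledger.record(lid, "STRAND_DISCARD", "PASS", dec.final)
                if dec.final == FLIP:
                    # Map the flipped dataset's genotypes onto the reference
                    # strand: g -> 2 - g for its rows; the merged panel keeps
                    # the reference allele designation.
                    j = combined.locus_index(lid)
                    for ds in dec.datasets_to_flip:
                        rows = combined.rows_for(dataset=ds)
                        col = combined.dosages[rows, j]
                        mask = col != MISSING
                        col[mask] = 2 - col[mask]
                        combined.dosages[rows, j] = col
        n_flips = sum(
            len(d.datasets_to_flip)
            for d in resolution.decisions.values()
            if d.final == FLIP
        )
        logger.info("strand resolution: %s", resolution.counts())
        logger.info("applied %d (locus, dataset) strand flips", n_flips)

    if not config.fst_screen_before_strand:
        replicate_fst_screen(
            pairs, combined, ledger, config.fst_quantile, config.fst_max_pairs_allowed
        )

    retained = [l for l in shared if not ledger.is_discarded(l)]
    for lid in retained:
        ledger.retain(lid)
    ledger.validate()

    merged = combined.subset_loci(retained)
    summary = {
        "n_panels": len(panels),
        "n_unique_loci": len(
            set().union(*(set(p.locus_ids) for p in panels))
        ),
        "n_shared": len(shared),
        "n_conflicts": len(conflicts),
        "n_retained": len(retained),
        "n_discarded_shared": len(shared) - len(retained),
        "discards_by_rule": ledger.counts_by_rule(),
        "selected_threshold": calibration.selected_threshold,
        "strand_decisions": resolution.counts() if resolution else None,
    }
    logger.info("harmonization complete: %d loci retained", len(retained))
    return HarmonizationResult(merged, ledger, calibration, resolution, summary)
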