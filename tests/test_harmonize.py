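"""Harmonization stages: intersection, calibration, resolution, QC filters."""

import numpy as np
import pytest

import snpharmony as sh
from snpharmony.harmonize import (
    DISCARD,
    DISCARDED,
    FLIP,
    KEEP_AS_IS,
    QCLedger,
    ReplicatePair,
    calibrate_strand_threshold,
    filter_missingness,
    hwe_filter,
    intersect_panels,
    is_ambiguous,
    replicate_fst_screen,
    resolve_ambiguous_strands,
    run_harmonization,
)
from snpharmony.panel import MISSING, GenotypePanel, LocusDef, PanelError, SampleUnit

from conftest import make_panel


def dosages_for_allele_count(n_ind, count):
    """Dosage column over n_ind individuals with exactly `count` copies of
    the designated allele (of 2*n_ind)."""
    col = [2] * (count // 2) + [1] * (count % 2)
    col += [0] * (n_ind - len(col))
    return col


def panel_with_freqs(freq_by_loc, allele_pairs, dataset, n_ind=50, locus_ids=None):
    """Panel whose observed designated-allele frequencies are exact."""
    locations = list(freq_by_loc)
    n_loci = len(next(iter(freq_by_loc.values())))
    if locus_ids is None:
        locus_ids = [f"L{j:03d}" for j in range(n_loci)]
    loci = [LocusDef(lid, pair) for lid, pair in zip(locus_ids, allele_pairs)]
    rows = []
    individuals = []
    samples = []
    for loc in locations:
        block = np.column_stack(
            [
                dosages_for_allele_count(n_ind, round(2 * n_ind * f))
                for f in freq_by_loc[loc]
            ]
        ).astype(np.int8)
        rows.append(block)
        individuals.extend((f"{dataset}_{loc}_{k}", loc) for k in range(n_ind))
        samples.append(SampleUnit(loc, dataset, n_ind))
    return GenotypePanel(loci, samples, individuals, np.vstack(rows))


# ------------------------------------------------------------------ ambiguity
def test_is_ambiguous_classification():
    assert is_ambiguous(LocusDef("x", ("A", "T")))
    assert is_ambiguous(LocusDef("x", ("C", "G")))
    assert is_ambiguous(LocusDef("x", ("G", "C")))
    assert not is_ambiguous(LocusDef("x", ("A", "C")))
    assert not is_ambiguous(LocusDef("x", ("G", "T")))


# ------------------------------------------------------------ allele frequency
def test_allele_frequency_direct_counts():
    panel = make_panel(np.array([[0, 2, 0], [0, 2, 1], [0, MISSING, 1], [0, MISSING, 2]]))
    assert sh.allele_frequency(panel, "LOC", "L000") == (0.0, 4)
    assert sh.allele_frequency(panel, "LOC", "L001") == (1.0, 2)
    assert sh.allele_frequency(panel, "LOC", "L002") == (0.5, 4)


def test_allele_frequency_no_calls_is_nan_not_an_exception():
    panel = make_panel(np.array([[MISSING], [MISSING]]))
    f, n = sh.allele_frequency(panel, "LOC", "L000")
    assert n == 0 and np.isnan(f)


# ---------------------------------------------------------------- intersection
def test_intersection_is_set_intersection():
    p1 = make_panel(np.zeros((2, 3), np.int8), locus_ids=["a", "b", "c"], dataset="D1")
    p2 = make_panel(np.zeros((2, 3), np.int8), locus_ids=["b", "c", "d"], dataset="D2")
    p3 = make_panel(np.zeros((2, 2), np.int8), locus_ids=["c", "b"], dataset="D3")
    shared, private, conflicts, _ = intersect_panels([p1, p2, p3])
    assert set(shared) == {"b", "c"}
    assert private[0] == ["a"] and private[1] == ["d"] and private[2] == []
    assert conflicts == []


def test_reverse_complement_pairs_are_reconciled_with_dosage_recode():
    # G/T in panel 1; the same locus loaded as A/C (lower-code designation)
    # in panel 2 is its reverse complement with the designation swapped.
    p1 = make_panel([[2], [1]], allele_pairs=[("G", "T")], dataset="D1")
    p2 = make_panel([[2], [0]], allele_pairs=[("A", "C")], dataset="D2")
    shared, _, conflicts, aligned = intersect_panels([p1, p2])
    assert shared == ["L000"] and conflicts == []
    assert aligned[1].locus("L000").allele_pair == ("G", "T")
    assert list(aligned[1].dosages[:, 0]) == [0, 2]  # g -> 2 - g


def test_reverse_complement_same_designation_relabels_without_recode():
    p1 = make_panel([[2], [1]], allele_pairs=[("G", "T")], dataset="D1")
    p2 = make_panel([[2], [0]], allele_pairs=[("C", "A")], dataset="D2")
    _, _, _, aligned = intersect_panels([p1, p2])
    assert aligned[1].locus("L000").allele_pair == ("G", "T")
    assert list(aligned[1].dosages[:, 0]) == [2, 0]


def test_irreconcilable_allele_pairs_go_to_conflicts():
    p1 = make_panel([[1]], allele_pairs=[("A", "C")], dataset="D1",
                    locus_ids=["x"])
    p2 = make_panel([[1]], allele_pairs=[("A", "G")], dataset="D2",
                    locus_ids=["x"])
    p1b = make_panel([[1]], allele_pairs=[("A", "C")], dataset="D1",
                     locus_ids=["x", ]).subset_loci(["x"])
    with pytest.raises(PanelError, match="no shared loci"):
        intersect_panels([p1, p2])
    # with another shared locus the conflict is quarantined, not fatal
    p1 = make_panel(np.zeros((1, 2), np.int8), allele_pairs=[("A", "C")] * 2,
                    locus_ids=["x", "y"], dataset="D1")
    p2 = make_panel(np.zeros((1, 2), np.int8),
                    allele_pairs=[("A", "G"), ("A", "C")],
                    locus_ids=["x", "y"], dataset="D2")
    shared, _, conflicts, _ = intersect_panels([p1, p2])
    assert conflicts == ["x"] and shared == ["y"]


# ----------------------------------------------------------------- calibration
def _one_locale_panels(ref_freqs, alt_freqs, pairs_kinds=None):
    n = len(ref_freqs)
    kinds = pairs_kinds or [("A", "C")] * n
    ref = panel_with_freqs({"R1": ref_freqs}, kinds, "REF")
    alt = panel_with_freqs({"A1": alt_freqs}, kinds, "ALT")
    pair = ReplicatePair("IRE", ("R1", "REF"), ("A1", "ALT"))
    return [ref, alt], [pair]


def test_calibration_hand_enumeration():
    panels, pairs = _one_locale_panels([0.10, 0.20, 0.30, 0.40],
                                       [0.12, 0.21, 0.78, 0.41])
    cal = calibrate_strand_threshold(pairs, panels, ["L000", "L001", "L002", "L003"])
    g45 = cal.grid.index(0.45)
    assert cal.error_rate["IRE"][g45] == pytest.approx(1 / 4)
    assert cal.confidence("IRE")[g45] == pytest.approx(0.75)
    # cumulative: at 0.25 only the two matching low-MAF loci are binned
    g25 = cal.grid.index(0.25)
    assert cal.error_rate["IRE"][g25] == 0.0
    assert cal.selected_threshold == 0.25


def test_perfect_agreement_selects_grid_maximum():
    rng = np.random.default_rng(5)
    freqs = rng.uniform(0.02, 0.98, size=200).round(2).tolist()
    ref = panel_with_freqs({"R1": freqs, "R2": freqs, "R3": freqs},
                           [("A", "C")] * 200, "REF")
    alt = panel_with_freqs({"A1": freqs, "A2": freqs, "A3": freqs},
                           [("A", "C")] * 200, "ALT")
    pairs = [
        ReplicatePair(f"LOC{i}", (f"R{i}", "REF"), (f"A{i}", "ALT"))
        for i in (1, 2, 3)
    ]
    cal = calibrate_strand_threshold(pairs, [ref, alt], ref.locus_ids)
    assert cal.selected_threshold == 0.45
    assert np.all(cal.mean_confidence == 1.0)


def test_total_mismatch_selects_no_threshold():
    ref_freqs = [0.04, 0.10, 0.20, 0.30, 0.40, 0.45]
    alt_freqs = [1 - f for f in ref_freqs]
    panels, pairs = _one_locale_panels(ref_freqs, alt_freqs)
    cal = calibrate_strand_threshold(pairs, panels,
                                     [f"L{j:03d}" for j in range(6)])
    assert cal.selected_threshold is None
    assert np.all(cal.error_rate["IRE"] == 1.0)


def test_calibration_insensitive_to_locus_order():
    panels, pairs = _one_locale_panels([0.10, 0.20, 0.30, 0.40],
                                       [0.12, 0.21, 0.78, 0.41])
    loci = ["L000", "L001", "L002", "L003"]
    a = calibrate_strand_threshold(pairs, panels, loci)
    b = calibrate_strand_threshold(pairs, panels, loci[::-1])
    assert a.selected_threshold == b.selected_threshold
    assert np.array_equal(a.error_rate["IRE"], b.error_rate["IRE"])


def test_selected_threshold_nonincreasing_in_requirement():
    panels, pairs = _one_locale_panels(
        [0.04, 0.10, 0.20, 0.30, 0.40], [0.06, 0.11, 0.22, 0.72, 0.42]
    )
    loci = [f"L{j:03d}" for j in range(5)]
    prev = 1.0
    for req in (0.5, 0.7, 0.9, 0.99):
        cal = calibrate_strand_threshold(pairs, panels, loci,
                                         confidence_requirement=req)
        t = -1.0 if cal.selected_threshold is None else cal.selected_threshold
        assert t <= prev
        prev = t


# ------------------------------------------------------------------ resolution
def _resolution_panels(f_ref_by_locale, f_alt_by_locale):
    pairs_ct = [("A", "T")]
    ref = panel_with_freqs(
        {f"R{i}": [f] for i, f in enumerate(f_ref_by_locale)}, pairs_ct, "REF"
    )
    alt = panel_with_freqs(
        {f"A{i}": [f] for i, f in enumerate(f_alt_by_locale)}, pairs_ct, "ALT"
    )
    pairs = [
        ReplicatePair(f"LOC{i}", (f"R{i}", "REF"), (f"A{i}", "ALT"))
        for i in range(len(f_ref_by_locale))
    ]
    return [ref, alt], pairs


def test_clear_flip_at_every_locale_is_corrected():
    panels, pairs = _resolution_panels([0.10] * 3, [0.90] * 3)
    res = resolve_ambiguous_strands(pairs, panels, ["L000"], 0.45)
    dec = res.decisions["L000"]
    assert dec.final == FLIP and dec.datasets_to_flip == {"ALT"}


def test_matched_frequencies_keep_locus_as_is():
    panels, pairs = _resolution_panels([0.10] * 3, [0.12] * 3)
    res = resolve_ambiguous_strands(pairs, panels, ["L000"], 0.45)
    assert res.decisions["L000"].final == KEEP_AS_IS


def test_inconsistent_consensus_discards():
    panels, pairs = _resolution_panels([0.10, 0.10, 0.10], [0.90, 0.12, 0.90])
    res = resolve_ambiguous_strands(pairs, panels, ["L000"], 0.45)
    dec = res.decisions["L000"]
    assert [dec.verdicts[f"LOC{i}"] for i in range(3)] == ["FLIPPED", "MATCHED", "FLIPPED"]
    assert dec.final == DISCARD


def test_band_frequency_is_inconclusive_and_discards_under_strict_consensus():
    panels, pairs = _resolution_panels([0.10, 0.50, 0.10], [0.90, 0.50, 0.90])
    res = resolve_ambiguous_strands(pairs, panels, ["L000"], 0.45)
    assert res.decisions["L000"].verdicts["LOC1"] == "INCONCLUSIVE"
    assert res.decisions["L000"].final == DISCARD
    relaxed = resolve_ambiguous_strands(pairs, panels, ["L000"], 0.45,
                                        consensus="majority")
    assert relaxed.decisions["L000"].final == FLIP


def test_unambiguous_locus_is_a_contract_error():
    panels, pairs = _one_locale_panels([0.1], [0.1])
    with pytest.raises(PanelError, match="not ambiguous"):
        resolve_ambiguous_strands(pairs, panels, ["L000"], 0.45)


# -------------------------------------------------------------- missingness QC
def _missing_panel(pattern_by_loc, n_loci=1):
    """pattern_by_loc: location -> list of per-individual missing bools per locus."""
    locations = {}
    i = 0
    for loc, mask in pattern_by_loc.items():
        locations[loc] = list(range(i, i + len(mask)))
        i += len(mask)
    n_ind = i
    dos = np.ones((n_ind, n_loci), dtype=np.int8)
    for loc, mask in pattern_by_loc.items():
        for k, r in enumerate(locations[loc]):
            if mask[k]:
                dos[r, 0] = MISSING
    return make_panel(dos, locations=locations)


def test_fully_typed_locus_is_retained():
    panel = _missing_panel({"A": [False] * 10, "B": [False] * 10})
    ledger = QCLedger()
    filter_missingness(panel, ledger)
    assert not ledger.is_discarded("L000")


def test_call_rate_at_or_below_060_in_one_location_fails_rule_a():
    panel = _missing_panel({"A": [True] * 5 + [False] * 5, "B": [False] * 10})
    ledger = QCLedger()
    filter_missingness(panel, ledger)  # 50% called in A
    assert ledger.is_discarded("L000")
    assert ledger.entries["L000"][0][0] == "MISSINGNESS_A"
    # boundary: exactly 60% called also fails ("<= 60%")
    panel = _missing_panel({"A": [True] * 4 + [False] * 6, "B": [False] * 10})
    ledger = QCLedger()
    filter_missingness(panel, ledger)
    assert ledger.is_discarded("L000")
    # just above the floor passes
    panel = _missing_panel({"A": [True] * 3 + [False] * 7, "B": [False] * 10})
    ledger = QCLedger()
    filter_missingness(panel, ledger)
    assert not ledger.is_discarded("L000")


def test_rule_b_boundary_more_than_five_locations():
    def build(n_bad):
        pattern = {}
        for i in range(10):
            bad = i < n_bad
            pattern[f"P{i}"] = [bad, bad] + [False] * 8  # 20% missing when bad
        return _missing_panel(pattern)

    ledger = QCLedger()
    filter_missingness(build(6), ledger)
    assert ledger.is_discarded("L000")
    assert any(r[0] == "MISSINGNESS_B" and r[1] == "FAIL"
               for r in ledger.entries["L000"])
    ledger = QCLedger()
    filter_missingness(build(5), ledger)
    assert not ledger.is_discarded("L000")


def test_lowering_call_rate_floor_never_discards_more(rng):
    dos = rng.integers(0, 3, size=(40, 30)).astype(np.int8)
    dos[rng.random(dos.shape) < 0.35] = MISSING
    panel = make_panel(dos, locations={"A": range(0, 20), "B": range(20, 40)})
    discarded = {}
    for floor in (0.8, 0.6, 0.4, 0.2):
        ledger = QCLedger()
        filter_missingness(panel, ledger, call_rate_floor=floor,
                           max_bad_samples=10**9)
        discarded[floor] = set(ledger.loci_with_status(DISCARDED))
    assert discarded[0.2] <= discarded[0.4] <= discarded[0.6] <= discarded[0.8]


# --------------------------------------------------------------------- HWE QC
def _hwe_panel(aberrant_locations):
    """6 locations x 30 individuals; locus 0 all-het in `aberrant_locations`
    locations, all other cells in perfect HWE-compatible monomorphism."""
    n_loci = 30
    locations = {f"P{i}": range(i * 30, (i + 1) * 30) for i in range(6)}
    dos = np.zeros((180, n_loci), dtype=np.int8)
    dos[:, 1:] = 2  # monomorphic -> p = 1 everywhere
    for i in range(6):
        rows = slice(i * 30, (i + 1) * 30)
        if i < aberrant_locations:
            dos[rows, 0] = 1  # every individual heterozygous
        else:
            # perfect HWE at p = 0.5: 7/15/8 approximates 7.5/15/7.5
            col = [2] * 7 + [1] * 15 + [0] * 8
            dos[rows, 0] = col
    return make_panel(dos, locations={k: list(v) for k, v in locations.items()})


def test_hwe_filter_discards_when_aberrant_in_four_locations():
    ledger = QCLedger()
    hwe_filter(_hwe_panel(4), ledger)
    assert ledger.is_discarded("L000")


def test_hwe_filter_retains_at_exactly_three_locations():
    ledger = QCLedger()
    hwe_filter(_hwe_panel(3), ledger)
    assert not ledger.is_discarded("L000")


def test_hwe_filter_passes_perfect_proportions():
    ledger = QCLedger()
    hwe_filter(_hwe_panel(0), ledger)
    assert ledger.loci_with_status(DISCARDED) == []


# ---------------------------------------------------------- replicate FST screen
def _screen_panel(outlier_sets, n_loci=100, n_pairs=3, n_ind=10):
    """Combined panel: pair k's two samples are identical (theta <= 0) except
    at its outlier loci, which carry a fixed difference (theta = 1)."""
    base = np.tile(np.array([[0], [2]], dtype=np.int8), (n_ind // 2, n_loci))
    locations, rows = {}, []
    samples_meta = []
    i = 0
    for k in range(n_pairs):
        a = base.copy()
        b = base.copy()
        for j in outlier_sets.get(k, []):
            a[:, j] = 0
            b[:, j] = 2
        for tag, block, ds in ((f"R{k}", a, "REF"), (f"A{k}", b, "ALT")):
            locations[tag] = list(range(i, i + n_ind))
            samples_meta.append((tag, ds))
            rows.append(block)
            i += n_ind
    dos = np.vstack(rows)
    loci = [LocusDef(f"l{j + 1}", ("A", "C")) for j in range(n_loci)]
    samples = [SampleUnit(loc, ds, n_ind) for loc, ds in samples_meta]
    individuals = []
    for loc, rws in locations.items():
        individuals.extend((f"{loc}_i{r}", loc) for r in rws)
    return GenotypePanel(loci, samples, individuals, dos)


def _screen_pairs(n_pairs):
    return [
        ReplicatePair(f"LOC{k}", (f"R{k}", "REF"), (f"A{k}", "ALT"))
        for k in range(n_pairs)
    ]


def test_screen_discards_only_overlap_of_top_sets():
    outliers = {0: range(0, 5), 1: range(3, 8), 2: range(95, 100)}
    panel = _screen_panel(outliers)
    ledger = QCLedger()
    top = replicate_fst_screen(_screen_pairs(3), panel, ledger)
    assert top["LOC0"] == {"l1", "l2", "l3", "l4", "l5"}
    assert top["LOC1"] == {"l4", "l5", "l6", "l7", "l8"}
    assert top["LOC2"] == {"l96", "l97", "l98", "l99", "l100"}
    assert set(ledger.loci_with_status(DISCARDED)) == {"l4", "l5"}


def test_screen_single_pair_never_discards():
    panel = _screen_panel({0: range(0, 5)}, n_pairs=1)
    ledger = QCLedger()
    replicate_fst_screen(_screen_pairs(1), panel, ledger)
    assert ledger.loci_with_status(DISCARDED) == []


def test_screen_boundary_one_vs_two_pairs():
    # locus l1 in the top set of exactly one pair: retained
    panel = _screen_panel({0: [0], 1: range(5, 10), 2: range(10, 15)})
    ledger = QCLedger()
    replicate_fst_screen(_screen_pairs(3), panel, ledger)
    assert not ledger.is_discarded("l1")
    # in exactly two pairs: discarded
    panel = _screen_panel({0: [0], 1: [0], 2: range(10, 15)})
    ledger = QCLedger()
    replicate_fst_screen(_screen_pairs(3), panel, ledger)
    assert ledger.is_discarded("l1")


def test_screen_warns_when_quantile_is_unstable():
    panel = _screen_panel({}, n_loci=10, n_pairs=2)
    ledger = QCLedger()
    with pytest.warns(UserWarning, match="unstable"):
        replicate_fst_screen(_screen_pairs(2), panel, ledger)


# ----------------------------------------------------------------- end-to-end
def test_clean_run_retains_every_shared_locus():
    cfg = sh.SimulationConfig(
        seed=3, n_loci=250, n_populations=6, n_datasets=2, per_pop_n=30,
        replicate_locales=1, frac_ambiguous=0.0, frac_flipped=0.0,
        missing_rate_per_dataset=(0.0, 0.0),
    )
    panels, truth = sh.emit_datasets(cfg)
    pairs = [ReplicatePair(n, r, a) for n, r, a in truth.replicate_pairs]
    res = run_harmonization(panels, pairs)
    assert res.summary["n_retained"] == res.summary["n_shared"] == 250
    assert res.summary["selected_threshold"] is not None


def test_ledger_conservation_and_merged_panel_validity():
    cfg = sh.SimulationConfig(seed=4, n_loci=300, n_populations=9, per_pop_n=25,
                              private_loci_per_dataset=20)
    panels, truth = sh.emit_datasets(cfg)
    pairs = [ReplicatePair(n, r, a) for n, r, a in truth.replicate_pairs]
    res = run_harmonization(panels, pairs)
    s = res.summary
    assert s["n_retained"] + s["n_discarded_shared"] == s["n_shared"]
    assert s["n_unique_loci"] == 300 + 3 * 20
    # every candidate locus (shared and private) has exactly one final status
    all_loci = set().union(*(set(p.locus_ids) for p in panels))
    assert set(res.ledger.status) == all_loci
    assert set(res.merged_panel.locus_ids) == set(
        res.ledger.loci_with_status("RETAINED")
    )
    res.merged_panel.validate()
    res.ledger.validate()


def test_corrected_flips_restore_cross_dataset_frequency_agreement():
    cfg = sh.SimulationConfig(seed=9, n_loci=400, n_populations=9, per_pop_n=40,
                              missing_rate_per_dataset=(0, 0, 0))
    panels, truth = sh.emit_datasets(cfg)
    pairs = [ReplicatePair(n, r, a) for n, r, a in truth.replicate_pairs]
    res = run_harmonization(panels, pairs)
    merged = res.merged_panel
    retained = set(merged.locus_ids)
    checked = 0
    for dec in res.resolution.decisions.values():
        if dec.final != FLIP or dec.locus_id not in retained:
            continue
        for pair in pairs:
            if pair.sample_alt[1] not in dec.datasets_to_flip:
                continue
            f_ref, n_ref = merged.allele_frequency(pair.sample_ref[0], dec.locus_id)
            f_alt, n_alt = merged.allele_frequency(pair.sample_alt[0], dec.locus_id)
            n = min(n_ref, n_alt)
            fbar = max((f_ref + f_alt) / 2, 1 / (2 * n))
            # 4 sd of the difference of two binomial frequency estimates
            tol = 4 * np.sqrt(fbar * (1 - fbar) / n)
            assert abs(f_ref - f_alt) <= tol
            checked += 1
    assert checked > 50


def test_no_calibrated_threshold_discards_all_ambiguous_with_warning():
    # every unambiguous locus mismatched across datasets -> zero confidence
    ref_freqs = [0.04, 0.10, 0.20, 0.30, 0.40, 0.45, 0.10, 0.20]
    alt_freqs = [1 - f for f in ref_freqs[:6]] + ref_freqs[6:]
    kinds = [("A", "C")] * 6 + [("A", "T"), ("C", "G")]
    ref = panel_with_freqs({"R1": ref_freqs}, kinds, "REF", n_ind=20)
    alt = panel_with_freqs({"A1": alt_freqs}, kinds, "ALT", n_ind=20)
    pairs = [ReplicatePair("IRE", ("R1", "REF"), ("A1", "ALT"))]
    with pytest.warns(UserWarning, match="no MAF threshold"):
        res = run_harmonization([ref, alt], pairs)
    assert res.summary["selected_threshold"] is None
    assert res.resolution is None
    for lid in ("L006", "L007"):
        assert res.ledger.is_discarded(lid)
        assert res.ledger.entries[lid][-1][0] == "STRAND_DISCARD"


def test_run_requires_panels_and_pairs():
    cfg = sh.SimulationConfig(seed=1, n_loci=50, n_populations=6, n_datasets=2,
                              replicate_locales=1)
    panels, truth = sh.emit_datasets(cfg)
    pairs = [ReplicatePair(n, r, a) for n, r, a in truth.replicate_pairs]
    with pytest.raises(PanelError):
        run_harmonization(panels[:1], pairs)
    with pytest.raises(PanelError):
        run_harmonization(panels, [])
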