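"""Emission model, recombination fractions, anchoring, Viterbi decoding."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pgtm import simulate as sim
from pgtm.phasing import (
    _N_SWITCH,
    _transition_logs,
    DELETION_HEMI,
    DOUBLE_HET,
    EmissionModel,
    MATERNAL_ONLY,
    PATERNAL_ONLY,
    anchor_parental_phase,
    decode_paths,
    detect_ploidy_failure,
    emission_matrix,
    emission_prob,
    recombination_fraction,
    resolve_deletion_origin,
    select_informative_snps,
    viterbi_decode,
)
from pgtm.types import (
    ALT,
    DELETED,
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    REF,
    GeneticMap,
)


# ---------------------------------------------------------------------------
# Emission model
# ---------------------------------------------------------------------------

class TestEmission:
    def test_noise_free_het_is_certain(self):
        assert emission_prob(EmissionModel(0.0, 0.0), HET, HET) == 1.0

    def test_dropout_to_homozygote(self):
        # true het observed hom_ref: (a + e) / 2 = (0.1 + 0.02) / 2
        m = EmissionModel(0.1, 0.02)
        assert emission_prob(m, HET, HOM_REF) == pytest.approx(0.06)

    @given(a=st.floats(0, 0.5), e=st.floats(0, 0.4))
    @settings(max_examples=100, derandomize=True)
    def test_each_conditional_distribution_sums_to_one(self, a, e):
        m = EmissionModel(a, e)
        for true in (HOM_REF, HET, HOM_ALT):
            total = sum(emission_prob(m, true, o) for o in (HOM_REF, HET, HOM_ALT))
            assert total == pytest.approx(1.0)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            EmissionModel(0.7, 0.4)

    def test_missing_observation_is_uninformative(self):
        m = EmissionModel(0.2, 0.05)
        assert all(emission_prob(m, t, MISSING) == 1.0 for t in (0, 1, 2))


# ---------------------------------------------------------------------------
# Recombination fraction
# ---------------------------------------------------------------------------

def _uniform_map(rate=1.0, lo=1, hi=20_000_000):
    return sim.uniform_genetic_map("chr2", lo, hi, rate)


class TestRecombinationFraction:
    def test_zero_distance_gives_zero(self):
        gmap = _uniform_map(rate=0.0)
        assert recombination_fraction(gmap, 100, 200) == 0.0

    def test_haldane_closed_form(self):
        # 0.01 cM = 1e-4 Morgan: r = (1 - exp(-2e-4)) / 2
        gmap = _uniform_map(rate=1.0)
        r = recombination_fraction(gmap, 1_000_000, 1_010_000)
        assert r == pytest.approx(0.5 * (1 - math.exp(-2e-4)), rel=1e-9)
        assert r == pytest.approx(9.999e-5, rel=1e-3)

    def test_monotone_and_bounded(self, rng):
        gmap = _uniform_map(rate=1.5)
        pairs = np.sort(rng.integers(1, 20_000_000, size=(1000, 2)), axis=1)
        pairs = pairs[pairs[:, 0] < pairs[:, 1]]
        rs = np.array([recombination_fraction(gmap, int(a), int(b)) for a, b in pairs])
        d = (pairs[:, 1] - pairs[:, 0]).astype(float)
        order = np.argsort(d)
        assert np.all(np.diff(rs[order]) >= -1e-12)
        assert np.all((rs >= 0) & (rs < 0.5))

    def test_unordered_positions_rejected(self):
        with pytest.raises(ValueError):
            recombination_fraction(_uniform_map(), 200, 100)


# ---------------------------------------------------------------------------
# Marker selection
# ---------------------------------------------------------------------------

class TestMarkerSelection:
    def test_classification_definitions(self, rng):
        truth, genotypes, _ = sim_family_small(rng)
        markers = select_informative_snps(genotypes, truth.scenario.variant,
                                          5_000_000)
        fgt = genotypes.sample_gt("father")
        mgt = genotypes.sample_gt("mother")
        for mk in markers:
            f, m = int(fgt[mk.site_index]), int(mgt[mk.site_index])
            if mk.klass == PATERNAL_ONLY:
                assert f == HET and m != HET
            elif mk.klass == MATERNAL_ONLY:
                assert m == HET and f != HET
            elif mk.klass == DOUBLE_HET:
                assert f == HET and m == HET

    def test_count_matches_brute_force_rescan(self, rng):
        truth, genotypes, _ = sim_family_small(rng, n_markers=200)
        v = truth.scenario.variant
        markers = select_informative_snps(genotypes, v, 5_000_000)
        fgt = genotypes.sample_gt("father")
        mgt = genotypes.sample_gt("mother")
        pos = genotypes.sites["pos"].to_numpy()
        expected = 0
        for i in range(genotypes.n_sites):
            if abs(int(pos[i]) - v.anchor_pos) > 5_000_000:
                continue
            f, m = int(fgt[i]), int(mgt[i])
            if f == MISSING or m == MISSING:
                continue
            if f == HET or m == HET:
                expected += 1
        assert len(markers) == expected

    def test_no_markers_raises(self):
        import pandas as pd
        from pgtm.types import GenotypeTable
        t = GenotypeTable(
            sites=pd.DataFrame({"chrom": ["chr2"], "pos": [8_000_000],
                                "ref": ["A"], "alt": ["G"]}),
            gt=np.array([[HOM_REF, HOM_REF, HOM_REF]], dtype=np.int8),
            samples=["father", "mother", "E1"],
        )
        with pytest.raises(ValueError, match="no informative markers"):
            select_informative_snps(t, sim.CUL3_VARIANT, 5_000_000)


def sim_family_small(rng, n_markers=60, ado=0.0, err=0.0, n_embryos=3):
    scn = sim.SimScenario(variant=sim.CUL3_VARIANT, n_markers=n_markers,
                          n_embryos=n_embryos, ado_rate=ado, genotype_error=err,
                          forced_transmission={0: (0, None)})
    truth = sim.simulate_family(scn, rng)
    genotypes = sim.observe_genotypes(truth, ado, err, rng)
    return truth, genotypes, scn


# ---------------------------------------------------------------------------
# Anchoring
# ---------------------------------------------------------------------------

def _phase_family(truth, genotypes, window=5_000_000, model=None):
    from pgtm.types import DirectTestResult
    v = truth.scenario.variant
    markers = select_informative_snps(genotypes, v, window)
    idx = np.array([m.site_index for m in markers])
    pid = truth.embryos[0].embryo_id
    direct = DirectTestResult(pid, truth.embryos[0].true_status(v))
    proband_obs = genotypes.sample_gt(pid)[idx]
    phased = anchor_parental_phase(markers, proband_obs, direct, v,
                                   model or EmissionModel(0.0, 0.0))
    obs = {e.embryo_id: genotypes.sample_gt(e.embryo_id)[idx]
           for e in truth.embryos}
    return phased, obs, idx


class TestAnchoring:
    def test_transmitted_allele_is_labelled_mutant_linked(self):
        """Father A/G, mother A/A, proband (paternal dominant carrier)
        observed A/G: the transmitted G is the mutant-linked allele."""
        import pandas as pd
        from pgtm.types import DirectTestResult, GenotypeTable
        t = GenotypeTable(
            sites=pd.DataFrame({"chrom": ["chr2"], "pos": [8_100_000],
                                "ref": ["A"], "alt": ["G"]}),
            gt=np.array([[HET, HOM_REF, HET]], dtype=np.int8),
            samples=["father", "mother", "E1"],
        )
        markers = select_informative_snps(t, sim.CUL3_VARIANT, 5_000_000)
        phased = anchor_parental_phase(
            markers, np.array([HET]), DirectTestResult("E1", "carrier"),
            sim.CUL3_VARIANT)
        assert markers[0].father_haps == (ALT, REF)  # M allele = G
        assert markers[0].father_provenance == "proband"

    def test_proband_missing_leaves_marker_unresolved(self):
        import pandas as pd
        from pgtm.types import DirectTestResult, GenotypeTable
        t = GenotypeTable(
            sites=pd.DataFrame({"chrom": ["chr2"], "pos": [8_100_000],
                                "ref": ["A"], "alt": ["G"]}),
            gt=np.array([[HET, HOM_REF, MISSING]], dtype=np.int8),
            samples=["father", "mother", "E1"],
        )
        markers = select_informative_snps(t, sim.CUL3_VARIANT, 5_000_000)
        anchor_parental_phase(markers, np.array([MISSING]),
                              DirectTestResult("E1", "carrier"), sim.CUL3_VARIANT)
        assert markers[0].father_haps is None
        assert markers[0].father_provenance == "unresolved"

    def test_non_carrier_proband_rejected(self):
        from pgtm.types import DirectTestResult
        with pytest.raises(ValueError, match="does not carry"):
            anchor_parental_phase([], np.array([]),
                                  DirectTestResult("E1", "wild_type"),
                                  sim.CUL3_VARIANT)

    def test_noise_free_anchoring_recovers_truth_everywhere(self, rng):
        """With a = e = 0 and no proband crossover, every anchorable marker's
        M allele equals the simulator's true carrier haplotype allele."""
        for _ in range(5):
            truth, genotypes, _ = sim_family_small(rng)
            if truth.embryos[0].crossovers["father"]:
                continue  # anchoring assumes no proband crossover
            phased, _, _ = _phase_family(truth, genotypes)
            checked = 0
            for k, mk in enumerate(phased.markers):
                if mk.father_provenance == "proband":
                    assert mk.father_haps[0] == truth.father_haps[0, _marker_row(truth, mk)]
                    checked += 1
            assert checked > 0

    def test_double_het_markers_are_never_anchored(self, rng):
        truth, genotypes, _ = sim_family_small(rng, n_markers=80)
        phased, _, _ = _phase_family(truth, genotypes)
        for mk in phased.markers:
            if mk.klass == DOUBLE_HET:
                assert mk.father_provenance in ("unresolved", "inferred")
                assert mk.mother_provenance in ("unresolved", "inferred")


def _marker_row(truth, mk):
    pos = truth.markers["pos"].to_numpy()
    return int(np.flatnonzero(pos == mk.pos)[0])


# ---------------------------------------------------------------------------
# Viterbi decoding
# ---------------------------------------------------------------------------

def enumerate_paths_oracle(log_emis, trans_logs):
    """Brute-force enumeration over all 4^n paths with the same tie-break
    rule as the decoder: max log-probability, then fewest haplotype
    switches, then lexicographically smallest state sequence."""
    n = log_emis.shape[0]
    n_paths = 4 ** n
    idx = np.arange(n_paths)
    P = np.empty((n_paths, n), dtype=np.int8)
    for k in range(n):
        P[:, k] = (idx // 4 ** (n - 1 - k)) % 4
    score = np.full(n_paths, -math.log(4.0))
    for k in range(n):
        score = score + log_emis[k][P[:, k]]
    switches = np.zeros(n_paths, dtype=int)
    for k in range(n - 1):
        score = score + trans_logs[k][P[:, k], P[:, k + 1]]
        switches += _N_SWITCH[P[:, k], P[:, k + 1]]
    tol = 1e-9 * max(n, 1)
    best = score.max()
    cand = np.flatnonzero(score >= best - tol)
    ranked = sorted(cand, key=lambda i: (switches[i], tuple(P[i])))
    return best, P[ranked[0]].copy()


def random_instance(rng, n_markers, model):
    """Random phased-marker set + embryo observations for oracle testing."""
    import pandas as pd
    positions = np.sort(rng.choice(np.arange(1, 5_000_000), n_markers, replace=False))
    trans_logs = []
    gmap = sim.uniform_genetic_map("chr1", 1, 5_000_000, 1.0)
    for k in range(n_markers - 1):
        r = recombination_fraction(gmap, int(positions[k]), int(positions[k + 1]))
        trans_logs.append(_transition_logs(r))
    # random phased parental alleles and observations
    logE = np.log(np.clip(rng.uniform(0.01, 1.0, size=(n_markers, 4)), 1e-12, None))
    return logE, trans_logs


class TestViterbi:
    def test_two_marker_hand_computed_trellis(self):
        """Noise-free 2-marker case: observations consistent only with state
        (M, M) at both markers; log-prob is log(1/4) + 2 log(stay)^2 terms."""
        r = 0.01
        trans = [_transition_logs(r)]
        logE = np.log(np.array([[1.0, 1e-9, 1e-9, 1e-9],
                                [1.0, 1e-9, 1e-9, 1e-9]]))
        path, lp, margin = viterbi_decode(logE, trans)
        np.testing.assert_array_equal(path, [0, 0])
        assert lp == pytest.approx(math.log(0.25) + 2 * math.log(1 - r), abs=1e-9)
        assert margin > 0

    def test_matches_exhaustive_enumeration(self, rng):
        model = EmissionModel(0.05, 0.01)
        for _ in range(60):
            n = int(rng.integers(2, 9))
            logE, trans = random_instance(rng, n, model)
            path, lp, _ = viterbi_decode(logE, trans)
            lp_oracle, path_oracle = enumerate_paths_oracle(logE, trans)
            assert lp == pytest.approx(lp_oracle, abs=1e-9)
            np.testing.assert_array_equal(path, path_oracle)

    def test_tie_break_prefers_fewer_switches_then_m(self):
        # uninformative emissions and symmetric transitions: the all-M path
        # (state 0 everywhere) must win by the deterministic tie-break
        n = 4
        logE = np.zeros((n, 4))
        trans = [_transition_logs(0.5 - 1e-12)] * (n - 1)
        path, _, _ = viterbi_decode(logE, trans)
        np.testing.assert_array_equal(path, np.zeros(n))

    def test_decoded_proband_is_self_consistent(self, rng):
        """Noise-free: the proband's own decoded path equals the expected
        anchored indicators at every proband-anchored marker."""
        truth, genotypes, _ = sim_family_small(rng)
        phased, obs, _ = _phase_family(truth, genotypes)
        model = EmissionModel(0.0, 0.0)
        gmap = truth.gmap
        paths, phased = decode_paths(phased, obs, model, gmap)
        pid = truth.embryos[0].embryo_id
        p = paths[pid]
        for k, mk in enumerate(phased.markers):
            if mk.father_provenance == "proband" and not p.skipped[k]:
                assert int(p.paternal[k]) == phased.proband_expected["father"]

    def test_all_missing_embryo_fails(self, rng):
        truth, genotypes, _ = sim_family_small(rng, n_embryos=2)
        phased, obs, _ = _phase_family(truth, genotypes)
        eid = truth.embryos[1].embryo_id
        obs[eid] = np.full_like(obs[eid], MISSING)
        paths, _ = decode_paths(phased, obs, EmissionModel(0.0, 0.0), truth.gmap)
        assert paths[eid].failed

    def test_margin_never_increases_with_ado_rate(self, rng):
        """Raising the assumed dropout rate can only blur the evidence: the
        posterior margin of a correctly decoded path must not grow."""
        truth, genotypes, _ = sim_family_small(rng, n_markers=40)
        margins = []
        for a in (0.01, 0.05, 0.10, 0.20):
            phased, obs, _ = _phase_family(truth, genotypes,
                                           model=EmissionModel(a, 0.01))
            paths, _ = decode_paths(phased, obs, EmissionModel(a, 0.01), truth.gmap)
            margins.append(paths[truth.embryos[1].embryo_id].margin)
        assert all(m2 <= m1 + 1e-9 for m1, m2 in zip(margins, margins[1:]))

    def test_breakpoint_count_equals_indicator_switches(self, rng):
        truth, genotypes, _ = sim_family_small(rng, n_markers=50, n_embryos=4)
        phased, obs, _ = _phase_family(truth, genotypes)
        paths, _ = decode_paths(phased, obs, EmissionModel(0.0, 0.0), truth.gmap)
        for p in paths.values():
            n_bp = len(p.breakpoints["father"]) + len(p.breakpoints["mother"])
            assert n_bp == p.n_switches


# ---------------------------------------------------------------------------
# Deletion-origin resolution
# ---------------------------------------------------------------------------

class TestDeletionOrigin:
    @pytest.mark.parametrize("origin", ["father", "mother"])
    def test_noise_free_origin_always_recovered(self, origin):
        """With >= 3 inside-deletion markers and no noise, the parental
        origin of the deletion is identified in every run."""
        from pgtm.types import SEA_DELETION, DirectTestResult
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(900 + seed)
            forced = {0: (0, 1)} if origin == "father" else {0: (1, 0)}
            scn = sim.SimScenario(variant=SEA_DELETION, n_markers=40,
                                  n_inside_markers=4, n_embryos=2,
                                  ado_rate=0.0, genotype_error=0.0,
                                  forced_transmission=forced)
            truth = sim.simulate_family(scn, rng)
            genotypes = sim.observe_genotypes(truth, 0.0, 0.0, rng)
            v = truth.scenario.variant
            markers = select_informative_snps(genotypes, v, 5_000_000)
            # this scenario may lack discriminating inside markers when the
            # parents' inside alleles coincide; require >= 1 deletion_hemi
            if not any(m.klass == DELETION_HEMI for m in markers):
                continue
            idx = np.array([m.site_index for m in markers])
            pid = truth.embryos[0].embryo_id
            got = resolve_deletion_origin(markers, genotypes.sample_gt(pid)[idx],
                                          EmissionModel(0.0, 0.0))
            assert got == origin
            hits += 1
        assert hits >= 5  # most seeds produce discriminating markers

    def test_recessive_without_inside_markers_errors_informatively(self):
        from pgtm.types import SEA_DELETION, DirectTestResult
        rng = np.random.default_rng(7)
        scn = sim.SimScenario(variant=SEA_DELETION, n_markers=40,
                              n_inside_markers=0, n_embryos=2,
                              ado_rate=0.0, genotype_error=0.0,
                              forced_transmission={0: (0, 1)})
        truth = sim.simulate_family(scn, rng)
        genotypes = sim.observe_genotypes(truth, 0.0, 0.0, rng)
        markers = select_informative_snps(genotypes, SEA_DELETION, 5_000_000)
        idx = np.array([m.site_index for m in markers])
        pid = truth.embryos[0].embryo_id
        with pytest.raises(ValueError, match="affected embryo"):
            anchor_parental_phase(markers, genotypes.sample_gt(pid)[idx],
                                  DirectTestResult(pid, "carrier"), SEA_DELETION)


# ---------------------------------------------------------------------------
# Ploidy gate
# ---------------------------------------------------------------------------

def _ploidy_family(rng, ploidy, n_markers=150):
    scn = sim.SimScenario(variant=sim.CUL3_VARIANT, n_markers=n_markers,
                          n_embryos=2, ado_rate=0.02, genotype_error=0.005,
                          ploidy={1: ploidy} if ploidy else {},
                          forced_transmission={0: (0, None)})
    truth = sim.simulate_family(scn, rng)
    genotypes = sim.observe_genotypes(truth, scn.ado_rate, scn.genotype_error, rng)
    return truth, genotypes


class TestPloidyGate:
    def test_normal_diploid_passes(self, rng):
        truth, genotypes = _ploidy_family(rng, None)
        for e in truth.embryos:
            assert detect_ploidy_failure(genotypes, e.embryo_id).ok

    def test_mi_triploid_fails(self, rng):
        truth, genotypes = _ploidy_family(rng, ("triploid", "MI"))
        st = detect_ploidy_failure(genotypes, truth.embryos[1].embryo_id)
        assert not st.ok

    def test_mii_triploid_fails_on_genotyping_qc(self, rng):
        truth, genotypes = _ploidy_family(rng, ("triploid", "MII"))
        st = detect_ploidy_failure(genotypes, truth.embryos[1].embryo_id)
        assert not st.ok and st.reason == "excess_nocalls"

    def test_monosomy_fails_mendelian_check(self, rng):
        truth, genotypes = _ploidy_family(rng, ("monosomy", "father"))
        st = detect_ploidy_failure(genotypes, truth.embryos[1].embryo_id)
        assert not st.ok

    def test_cnv_segment_on_variant_chromosome_fails(self, rng):
        import pandas as pd
        truth, genotypes = _ploidy_family(rng, None)
        segs = pd.DataFrame([{"chrom": "chr2", "start": 1, "end": 30_000_000,
                              "n_bins": 150, "mean_log2": 0.58, "z": 3.0,
                              "class": "gain", "scope": "whole_chromosome",
                              "level": 1.0}])
        st = detect_ploidy_failure(genotypes, truth.embryos[0].embryo_id,
                                   cnv_segments=segs, variant_chrom="chr2")
        assert not st.ok and st.reason == "cnv_aneuploid"
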