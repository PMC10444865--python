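"""Cohort statistics: normalization, ANCOVA, regressions, rank-sum strata."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from cspws.classify import roc_auc
from cspws.stats import (
    PatientD,
    age_adjust,
    ancova_d,
    average_d_auc,
    packyear_subgroup_test,
    patient_mean_d,
    subgroup_regression,
)


def _cell_table(rows):
    return pd.DataFrame(
        rows, columns=["patient_id", "group", "cell_mean_d", "keep"]
    ).assign(keep=lambda df: df["keep"].astype(bool))


def _patients(spec_args=None, n=200, seed=0):
    """Patient list straight from the generator's patient model."""
    from cspws.cohort import CohortSpec, sample_patient

    spec = CohortSpec(image_width=256, image_height=192,
                      **(spec_args or {}))
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        grp = "case" if i % 2 else "control"
        rec = sample_patient(spec, grp, rng, index=i)
        out.append(
            PatientD(
                patient_id=rec.patient_id, group=grp,
                mean_nuclear_d=rec.true_mean_d, normalized_d=np.nan,
                n_cells=30, age=rec.age, pack_years=rec.pack_years,
                gender=rec.gender, race=rec.race,
            )
        )
    ctrl = np.mean([p.mean_nuclear_d for p in out if p.group == "control"])
    for p in out:
        p.normalized_d = p.mean_nuclear_d / ctrl
    return out


class TestPatientMeanD:
    def test_self_normalization_to_one(self):
        rows = [("a", "control", 2.0, True)] * 3 + [("b", "case", 2.0, True)] * 3
        pts = patient_mean_d(_cell_table(rows))
        assert all(p.normalized_d == pytest.approx(1.0) for p in pts)

    def test_case_ratio(self):
        rows = [("a", "control", 2.0, True)] * 2 + [("b", "case", 2.2, True)] * 2
        pts = {p.patient_id: p for p in patient_mean_d(_cell_table(rows))}
        assert pts["b"].normalized_d == pytest.approx(1.1)

    def test_cell_order_invariance(self):
        rows = [("a", "control", v, True) for v in (1.9, 2.0, 2.3)] + [
            ("b", "case", v, True) for v in (2.2, 2.4)
        ]
        p1 = patient_mean_d(_cell_table(rows))
        p2 = patient_mean_d(_cell_table(rows[::-1]))
        d1 = {p.patient_id: p.normalized_d for p in p1}
        d2 = {p.patient_id: p.normalized_d for p in p2}
        assert d1 == pytest.approx(d2)

    def test_control_mean_fixed_point(self):
        pts = _patients(n=100, seed=3)
        ctrl = [p.normalized_d for p in pts if p.group == "control"]
        assert np.mean(ctrl) == pytest.approx(1.0, abs=1e-12)

    def test_zero_kept_cells_excluded_with_warning(self):
        rows = [("a", "control", 2.0, True), ("b", "case", 2.1, False)]
        with pytest.warns(UserWarning, match="no kept cells"):
            pts = patient_mean_d(_cell_table(rows))
        assert [p.patient_id for p in pts] == ["a"]


class TestAncova:
    def test_recovers_injected_age_slope(self):
        pts = _patients(n=500, seed=4)
        rep = ancova_d(pts)
        assert rep.terms["age"]["p"] < 0.05
        # CI on the age coefficient covers the injected -0.006 on the
        # normalized scale (divide by baseline ~2)
        slope = rep.terms["age"]["slope"]
        assert abs(slope - (-0.006 / 2.0)) < 0.0012

    def test_null_covariate_p_uniform(self):
        """pack-years is independent of D by construction; its ANCOVA
        p-values over replicates are uniform (KS, alpha = 0.01)."""
        pvals = []
        for rep in range(120):
            pts = _patients(n=80, seed=500 + rep)
            pvals.append(ancova_d(pts).terms["pack_years"]["p"])
        assert ss.kstest(pvals, "uniform").pvalue > 0.01

    def test_duplicated_covariate_rank_deficiency(self):
        pts = _patients(n=60, seed=6)
        df = pd.DataFrame(
            {
                "normalized_d": [p.normalized_d for p in pts],
                "group": [p.group for p in pts],
                "age": [p.age for p in pts],
                "age2": [p.age for p in pts],
            }
        )
        with pytest.raises(ValueError, match="collinear"):
            ancova_d(df, covariates=("group", "age", "age2"))

    def test_constant_covariate_rejected(self):
        pts = _patients(n=40, seed=7)
        for p in pts:
            p.race = "caucasian"
        with pytest.raises(ValueError, match="constant"):
            ancova_d(pts)

    def test_too_few_patients(self):
        with pytest.raises(ValueError):
            ancova_d(_patients(n=6, seed=8))


class TestSubgroupRegression:
    def test_constant_d_zero_slope(self):
        pts = _patients(n=50, seed=9)
        for p in pts:
            p.normalized_d = 1.0
        slope, _ = subgroup_regression(pts, "age")
        assert slope == pytest.approx(0.0, abs=1e-12)

    def test_noiseless_line_exact(self):
        pts = _patients(n=50, seed=10)
        for p in pts:
            p.normalized_d = 1.0 - 0.006 * (p.age - 60.0)
        slope, ci = subgroup_regression(pts, "age")
        assert slope == pytest.approx(-0.006, abs=1e-12)

    def test_recovers_default_control_slope(self):
        pts = _patients(n=1000, seed=11)
        slope, ci = subgroup_regression(
            pts, "age", lambda p: p.group == "control"
        )
        # injected slope on the normalized scale
        assert ci[0] <= -0.006 / 2.0 <= ci[1]

    def test_small_subgroup_rejected(self):
        pts = _patients(n=50, seed=12)
        with pytest.raises(ValueError):
            subgroup_regression(pts, "age", lambda p: p.age > 200)


class TestAgeAdjust:
    def test_zero_slope_is_identity(self):
        pts = _patients(n=30, seed=13)
        adj, flags = age_adjust(pts, 0.0)
        assert np.allclose(adj, [p.normalized_d for p in pts])
        assert flags.all()

    def test_residualization_kills_control_slope(self):
        pts = _patients(n=400, seed=14)
        slope, _ = subgroup_regression(pts, "age", lambda p: p.group == "control")
        adj, _ = age_adjust(pts, slope)
        ctrl = [p.group == "control" for p in pts]
        ages = np.array([p.age for p in pts])[ctrl]
        res = ss.linregress(ages, adj[ctrl])
        assert abs(res.slope) < 1e-12 + abs(slope) * 1e-6 + 1e-5

    def test_missing_age_flagged(self):
        pts = _patients(n=20, seed=15)
        pts[0].age = np.nan
        adj, flags = age_adjust(pts, -0.003)
        assert not flags[0] and flags[1:].all()
        assert adj[0] == pts[0].normalized_d


class TestAverageDAuc:
    def test_null_and_separated(self):
        pts = _patients({"effect_delta_d": 0.0, "age_slope_per_year": 0.0},
                        n=300, seed=16)
        assert 0.4 < average_d_auc(pts) < 0.6
        for p in pts:
            p.normalized_d = 2.0 if p.group == "case" else 1.0
        assert average_d_auc(pts) == 1.0

    def test_identical_to_rank_auc(self):
        pts = _patients(n=101, seed=17)
        scores = np.array([p.normalized_d for p in pts])
        labels = np.array([1 if p.group == "case" else 0 for p in pts])
        assert average_d_auc(pts) == roc_auc(scores, labels)


class TestPackyearStrata:
    def test_stratum_counts_match_filter(self):
        pts = _patients(n=120, seed=18)
        out = packyear_subgroup_test(pts)
        lo, hi = out["pky_lt_20"], out["pky_ge_20"]
        n_lo = sum(p.pack_years < 20 for p in pts)
        assert lo["n_case"] + lo["n_control"] == n_lo
        assert hi["n_case"] + hi["n_control"] == len(pts) - n_lo

    def test_complete_separation_matches_exact_enumeration(self):
        """With n = (7, 14) and complete separation, the rank-sum p equals
        the tail probability from the exact permutation distribution."""
        pts = []
        for i in range(7):
            pts.append(PatientD(f"c{i}", "control", 2.0, 1.0 + 0.001 * i, 30,
                                pack_years=5.0))
        for i in range(14):
            pts.append(PatientD(f"k{i}", "case", 2.2, 1.2 + 0.001 * i, 30,
                                pack_years=5.0))
        out = packyear_subgroup_test(pts)["pky_lt_20"]
        # brute-force: U statistic null distribution by enumeration
        vals = [p.normalized_d for p in pts]
        ranks = ss.rankdata(vals)
        case_ranks = ranks[7:]
        u_obs = case_ranks.sum() - 14 * 15 / 2
        count = 0
        total = 0
        for combo in itertools.combinations(range(21), 14):
            u = ranks[list(combo)].sum() - 14 * 15 / 2
            total += 1
            if abs(u - 49.0) >= abs(u_obs - 49.0):  # 49 = n1 n0 / 2
                count += 1
        assert out["p"] == pytest.approx(count / total, rel=1e-9)

    def test_empty_stratum_not_fatal(self):
        pts = [PatientD(f"p{i}", "case" if i % 2 else "control", 2.0,
                        1.0 + 0.01 * i, 30, pack_years=30.0) for i in range(10)]
        out = packyear_subgroup_test(pts)
        assert out["pky_lt_20"]["p"] is None
        assert out["pky_ge_20"]["p"] is not None
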