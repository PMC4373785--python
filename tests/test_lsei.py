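import numpy as np
import pytest

import limflux as lf
from limflux.lsei import LseiProblem, aggregate_fold_changes, rough_estimate
from oracles import lsei_oracle


class TestFoldChangeTable:
    def test_log2_to_linear(self):
        t = lf.FoldChangeTable({"g": -1.0}, "log2").to_linear()
        assert t.entries["g"] == pytest.approx(0.5)

    def test_nonpositive_linear_rejected(self):
        with pytest.raises(ValueError):
            lf.FoldChangeTable({"g": 0.0}, "linear")

    def test_csv_roundtrip(self, tmp_path):
        import pandas as pd

        p = tmp_path / "fc.csv"
        pd.DataFrame({"gene_id": ["g1", "g2"], "fold_change": [0.5, 2.0]}).to_csv(
            p, index=False
        )
        t = lf.FoldChangeTable.from_csv(p)
        assert t.entries == {"g1": 0.5, "g2": 2.0}


class TestAggregation:
    @pytest.mark.parametrize("policy,fc,expected", [
        ("average", {"g1": 1.2, "g2": 0.8}, 1.0),
        ("average", {"g1": 0.5}, 0.5),
        ("minimum", {"g1": 0.5}, 0.5),
        ("geometric_mean", {"g1": 0.5}, 0.5),
        ("geometric_mean", {"g1": 4.0, "g2": 1.0}, 2.0),
        ("minimum", {"g1": 4.0, "g2": 1.0}, 1.0),
    ])
    def test_policies(self, policy, fc, expected):
        out = aggregate_fold_changes(
            {"R": ["g1", "g2"]}, lf.FoldChangeTable(fc), policy=policy
        )
        assert out["R"] == pytest.approx(expected)

    def test_genes_without_data_skipped_within_reaction(self):
        out = aggregate_fold_changes(
            {"R": ["g1", "gX"]}, lf.FoldChangeTable({"g1": 2.0})
        )
        assert out["R"] == pytest.approx(2.0)

    def test_reaction_without_any_data_omitted(self):
        out = aggregate_fold_changes(
            {"R1": ["g1"], "R2": ["gX"]}, lf.FoldChangeTable({"g1": 2.0})
        )
        assert "R2" not in out

    def test_all_reactions_without_data_warns(self):
        with pytest.warns(UserWarning):
            out = aggregate_fold_changes(
                {"R": ["gX"]}, lf.FoldChangeTable({"g1": 2.0})
            )
        assert out == {}

    def test_structured_policy_min_over_and_mean_over_or(self):
        fc = lf.FoldChangeTable({"g1": 4.0, "g2": 1.0, "g3": 0.5})
        out = aggregate_fold_changes(
            {"R": "(g1 and g2) or g3"}, fc, structured=True
        )
        # min(4, 1) = 1 for the complex, mean(1, 0.5) over isoforms
        assert out["R"] == pytest.approx(0.75)


class TestRoughEstimate:
    def test_scaling(self):
        ref = lf.FluxVector({"R": 2.0})
        assert rough_estimate(ref, {"R": 0.5}) == {"R": 1.0}

    def test_sign_preserved_for_release_fluxes(self):
        ref = lf.FluxVector({"R": -0.013})
        assert rough_estimate(ref, {"R": 2.0})["R"] == pytest.approx(-0.026)

    def test_empty_map(self):
        assert rough_estimate(lf.FluxVector({"R": 1.0}), {}) == {}


class TestSolveLsei:
    def test_identity_projection_of_feasible_target(self):
        # A = I and b already satisfies the constraints: x = b exactly
        b = np.array([1.0, 2.0, 3.0])
        prob = LseiProblem(E=np.zeros((0, 3)), f=[], G=np.eye(3), h=np.zeros(3),
                           A=np.eye(3), b=b, reaction_labels=["a", "b", "c"])
        sol = lf.solve_lsei(prob)
        np.testing.assert_allclose(sol.to_array(["a", "b", "c"]), b, atol=1e-9)
        assert sol.objective_value == pytest.approx(0.0, abs=1e-14)

    def test_chain_target_on_middle_reaction(self, toy_chain):
        # steady state forces all three fluxes equal; targeting the middle
        # reaction at 0.5*v moves the whole chain there
        lim = lf.build_lim(toy_chain)
        A = np.array([[0.0, 1.0, 0.0]])
        prob = LseiProblem(E=lim.E, f=lim.f, G=lim.G, h=lim.h, A=A, b=[0.5],
                           reaction_labels=lim.reaction_labels)
        sol = lf.solve_lsei(prob)
        for rid in ("R1", "R2", "R3"):
            assert sol.values[rid] == pytest.approx(0.5, abs=1e-9)

    def test_infeasible_constraints(self):
        prob = LseiProblem(E=np.array([[1.0]]), f=[1.0], G=np.array([[-1.0]]),
                           h=[0.0], A=np.eye(1), b=[0.0])
        with pytest.raises(lf.InfeasibleProblemError):
            lf.solve_lsei(prob)

    def test_rank_deficiency_returns_min_norm(self):
        # A ignores x2 entirely; the minimum-norm tie-break sets it to 0
        prob = LseiProblem(E=np.zeros((0, 2)), f=[],
                           G=np.zeros((0, 2)), h=[],
                           A=np.array([[1.0, 0.0]]), b=[2.0],
                           reaction_labels=["x1", "x2"])
        sol = lf.solve_lsei(prob)
        assert sol.values["x1"] == pytest.approx(2.0, abs=1e-9)
        assert sol.values["x2"] == pytest.approx(0.0, abs=1e-9)

    def test_matches_active_set_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = 5
            x_true = rng.uniform(0.1, 1.0, n)
            E = rng.integers(-2, 3, size=(2, n)).astype(float)
            f = E @ x_true
            G = np.eye(n)
            h = np.zeros(n)
            A = rng.standard_normal((4, n))
            b = rng.standard_normal(4)
            prob = LseiProblem(E=E, f=f, G=G, h=h, A=A, b=b)
            sol = lf.solve_lsei(prob)
            best_val, best_x = lsei_oracle(E, f, G, h, A, b)
            assert sol.objective_value == pytest.approx(best_val, abs=1e-7)
            x = np.array([sol.values[k] for k in sol.values])
            assert np.linalg.norm(A @ x - b) ** 2 == pytest.approx(best_val, abs=1e-7)


class TestLseiFBA:
    def test_unit_fold_changes_return_reference(self, branched_toy):
        lim = lf.build_lim(branched_toy, fixed_fluxes={"R_in": 1.0})
        ref = lf.solve_fba(lim, lf.ObjectiveSpec({"R_out": 1.0}, "maximize"))
        fc = lf.FoldChangeTable({"ga": 1.0, "gb": 1.0})
        out = lf.lsei_fba(branched_toy, ref, fc)
        for rid in branched_toy.reaction_ids:
            assert out.values[rid] == pytest.approx(ref.values[rid], abs=1e-8)

    def test_halved_branch_shifts_to_sibling(self, branched_toy):
        # reference: branch a carries 0.8, branch b 0.2; halving a's gene
        # pulls a toward 0.4 while total throughput settles in between
        ref = lf.FluxVector({"R_in": 1.0, "R_a": 0.8, "R_b": 0.2, "R_out": 1.0})
        fc = lf.FoldChangeTable({"ga": 0.5, "gb": 1.0})
        out = lf.lsei_fba(branched_toy, ref, fc)
        # oracle over the reduced 2-D polytope (branch fluxes >= 0)
        lim = lf.build_lim(branched_toy)
        idx = {r: j for j, r in enumerate(lim.reaction_labels)}
        A = np.zeros((2, 4))
        A[0, idx["R_a"]] = 1.0
        A[1, idx["R_b"]] = 1.0
        best_val, best_x = lsei_oracle(lim.E, lim.f, lim.G, lim.h, A,
                                       [0.4, 0.2])
        x = out.to_array(lim.reaction_labels)
        assert np.sum((A @ x - [0.4, 0.2]) ** 2) == pytest.approx(best_val, abs=1e-8)
        assert out.values["R_a"] < ref.values["R_a"]

    def test_objective_monotonicity(self, branched_toy):
        ref = lf.FluxVector({"R_in": 1.0, "R_a": 0.8, "R_b": 0.2, "R_out": 1.0})
        fc = lf.FoldChangeTable({"ga": 0.5, "gb": 1.3})
        out = lf.lsei_fba(branched_toy, ref, fc)
        # attained residual never exceeds the feasible reference's residual
        targets = {"R_a": 0.8 * 0.5, "R_b": 0.2 * 1.3}
        ref_resid = sum((ref.values[r] - t) ** 2 for r, t in targets.items())
        assert out.objective_value <= ref_resid + 1e-12

    def test_scale_equivariance(self, branched_toy):
        fc = lf.FoldChangeTable({"ga": 0.5, "gb": 1.5})
        ref = lf.FluxVector({"R_in": 1.0, "R_a": 0.8, "R_b": 0.2, "R_out": 1.0})
        out1 = lf.lsei_fba(branched_toy, ref, fc)
        ref3 = lf.FluxVector({k: 3 * v for k, v in ref.values.items()})
        out3 = lf.lsei_fba(branched_toy, ref3, fc)
        for rid in branched_toy.reaction_ids:
            assert out3.values[rid] == pytest.approx(3 * out1.values[rid], abs=1e-8)
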