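import numpy as np
import pytest

from mia.datasets import MethodParams
from mia.modules import (
    MdModule,
    ModuleSet,
    extract_modules_nmf,
    extract_modules_pls,
    module_size_summary,
    module_stats,
)
from mia.nmf import FactorizationResult
from mia.pls import LatentComponentSet, PLSComponent
from mia.preprocess import nonneg_split


def make_result(W, H_list, method="jnmf"):
    return FactorizationResult(
        W=np.asarray(W, float),
        H_list=[np.asarray(H, float) for H in H_list],
        objective_trace=[1.0],
        restart_objectives=[1.0],
        params_used=MethodParams(n_modules=np.asarray(W).shape[1]),
        seed=0,
        method=method,
    )


@pytest.fixture
def planted_result(rng):
    """One factor, 100 samples of which 10 load at 10 and 90 near zero."""
    W = np.abs(rng.normal(0, 0.01, size=(100, 1)))
    W[:10, 0] = 10.0
    H = np.abs(rng.normal(0, 0.01, size=(1, 50)))
    H[0, :5] = 8.0
    return make_result(W, [H])


class TestExtractNmf:
    def test_planted_samples_recovered_exactly(self, planted_result):
        labels = [f"s{i}" for i in range(100)]
        mods = extract_modules_nmf(
            planted_result, labels, [[f"g{j}" for j in range(50)]], ["Gene"], [1.0, 1.0]
        )
        assert mods.modules[0].samples == {f"s{i}" for i in range(10)}
        assert mods.modules[0].members["Gene"] == {f"g{j}" for j in range(5)}

    def test_huge_threshold_empties_member_sets(self, planted_result):
        mods = extract_modules_nmf(
            planted_result,
            [f"s{i}" for i in range(100)],
            [[f"g{j}" for j in range(50)]],
            ["Gene"],
            [1e6, 1e6],
        )
        assert mods.modules[0].samples == set()
        assert mods.modules[0].members["Gene"] == set()

    def test_member_counts_non_increasing_in_thresholds(self, rng):
        W = np.abs(rng.normal(size=(60, 3)))
        H1 = np.abs(rng.normal(size=(3, 40)))
        H2 = np.abs(rng.normal(size=(3, 25)))
        res = make_result(W, [H1, H2])
        labels = [f"s{i}" for i in range(60)]
        flabels = [[f"a{j}" for j in range(40)], [f"b{j}" for j in range(25)]]
        prev = None
        for t in (0.0, 0.5, 1.0, 2.0, 4.0):
            mods = extract_modules_nmf(res, labels, flabels, ["A", "B"], [t, t, t])
            total = sum(
                len(m.samples) + sum(len(s) for s in m.members.values()) for m in mods
            )
            if prev is not None:
                assert total <= prev
            prev = total

    def test_threshold_length_mismatch_rejected(self, planted_result):
        with pytest.raises(ValueError, match="thrd_module"):
            extract_modules_nmf(
                planted_result, ["s"] * 100, [["g"] * 50], ["Gene"], [1.0]
            )

    def test_split_copies_merge_back_with_sign_annotation(self, rng):
        X = np.zeros((20, 4))
        X[:10, 0] = 5.0    # positive copy passes
        X[:10, 1] = -5.0   # negative copy passes
        split = nonneg_split(X)
        W = np.zeros((20, 1))
        W[:10, 0] = 1.0
        H = np.zeros((1, 8))
        H[0, 0] = 5.0  # g0 positive copy
        H[0, 5] = 5.0  # g1 negative copy
        res = make_result(W, [H])
        mods = extract_modules_nmf(
            res,
            [f"s{i}" for i in range(20)],
            [[f"g{j}" for j in range(4)]],
            ["Gene"],
            [1.0, 1.0],
            splits=[split],
        )
        mod = mods.modules[0]
        assert mod.members["Gene"] == {"g0", "g1"}
        assert mod.member_signs["Gene"] == {"g0": "+", "g1": "-"}

    def test_extraction_is_deterministic(self, planted_result):
        labels = [f"s{i}" for i in range(100)]
        flabels = [[f"g{j}" for j in range(50)]]
        a = extract_modules_nmf(planted_result, labels, flabels, ["G"], [1.0, 1.0])
        b = extract_modules_nmf(planted_result, labels, flabels, ["G"], [1.0, 1.0])
        assert a.to_member_table().equals(b.to_member_table())


def make_pls_set(w_arrays, q_arrays, t_arrays):
    comps = []
    for w, q, t in zip(w_arrays, q_arrays, t_arrays):
        w = np.asarray(w, float)
        q = np.asarray(q, float)
        t = np.asarray(t, float)
        comps.append(
            PLSComponent(w_list=[w], q=q, t_list=[t], t=t, u=t, b=None, p_list=[w])
        )
    return LatentComponentSet(
        components=comps,
        method="smbpls",
        params_used=MethodParams(n_modules=len(comps)),
        selected_lambda=0.1,
        selected_mu=0.1,
        selected_gammas=(0.0, 0.0),
    )


class TestExtractPls:
    def test_support_defines_feature_members(self):
        w = [0.0, 0.7, 0.0, -0.7, 0.1]
        q = [1.0, 0.0]
        t = [0.0] * 18 + [9.0, 9.0]
        result = make_pls_set([w], [q], [t])
        mods = extract_modules_pls(
            result,
            [f"s{i}" for i in range(20)],
            [[f"x{j}" for j in range(5)]],
            ["X"],
            ["y0", "y1"],
            "Y",
        )
        mod = mods.modules[0]
        assert mod.members["X"] == {"x1", "x3", "x4"}
        assert mod.member_signs["X"]["x3"] == "-"
        assert mod.members["Y"] == {"y0"}
        assert mod.samples == {"s18", "s19"}

    def test_dense_weights_make_every_feature_a_member(self, rng):
        w = rng.normal(size=6)
        q = rng.normal(size=4)
        t = rng.normal(size=30)
        mods = extract_modules_pls(
            make_pls_set([w], [q], [t]),
            [f"s{i}" for i in range(30)],
            [[f"x{j}" for j in range(6)]],
            ["X"],
            [f"y{j}" for j in range(4)],
            "Y",
        )
        assert len(mods.modules[0].members["X"]) == 6
        assert len(mods.modules[0].members["Y"]) == 4


class TestModuleStats:
    def test_counts_match_cardinalities_and_table_shape(self):
        mods = ModuleSet(
            modules=[
                MdModule(1, {"a", "b"}, {"G": {"g1"}, "M": set()}, "m", {}),
                MdModule(2, set(), {"G": {"g1", "g2"}, "M": {"x"}}, "m", {}),
            ],
            method="jnmf",
            feature_types=["G", "M"],
        )
        stats = module_stats(mods)
        assert len(stats) == 2 * (1 + 2)
        lookup = stats.set_index(["module_id", "member_type"])["count"]
        assert lookup[(1, "sample")] == 2
        assert lookup[(2, "G")] == 2
        assert lookup[(2, "M")] == 1
        summary = module_size_summary(stats)
        assert set(summary["member_type"]) == {"sample", "G", "M"}

    def test_empty_module_set_gives_empty_tables(self):
        mods = ModuleSet(modules=[], method="jnmf", feature_types=[])
        assert module_stats(mods).empty
        assert module_size_summary(module_stats(mods)).empty

    def test_duplicate_module_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            ModuleSet(
                modules=[
                    MdModule(1, set(), {}, "m", {}),
                    MdModule(1, set(), {}, "m", {}),
                ],
                method="jnmf",
                feature_types=[],
            )


class TestMemberTable:
    def test_round_trip_through_member_table(self):
        mods = ModuleSet(
            modules=[
                MdModule(1, {"s1"}, {"G": {"g1", "g2"}}, "m", {}),
                MdModule(2, {"s2", "s3"}, {"G": set()}, "m", {}),
            ],
            method="jnmf",
            feature_types=["G"],
        )
        back = ModuleSet.from_member_table(mods.to_member_table())
        assert back.modules[0].samples == {"s1"}
        assert back.modules[0].members["G"] == {"g1", "g2"}
        assert back.modules[1].samples == {"s2", "s3"}

    def test_member_list_folders_written(self, tmp_path):
        mods = ModuleSet(
            modules=[MdModule(1, {"s1"}, {"Gene": {"g1"}}, "m", {})],
            method="jnmf",
            feature_types=["Gene"],
        )
        mods.write_member_lists(tmp_path)
        assert (tmp_path / "GeneLists" / "module_01.txt").read_text() == "g1\n"
        assert (tmp_path / "SampleLists" / "module_01.txt").read_text() == "s1\n"
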