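"""Filter chain: RT window, organ-mean intensity filter, correlation pruning."""

import numpy as np
import pandas as pd
import pytest

import mbopls as m
from mbopls.features import AlignmentError, FeatureError

from conftest import tiny_block
from oracles import brute_force_intensity_filter, brute_force_prune


def meta(organs, sites=None):
    n = len(organs)
    return pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "tree_id": np.arange(n) + 1,
        "organ": organs,
        "site": sites or ["littoral"] * n,
    })


class TestRestrictRt:
    def test_closed_window_boundaries(self):
        block = tiny_block(np.ones((3, 4)), rts=[0.4, 0.5, 5.0, 5.1])
        kept = m.restrict_rt(block, m.FilterConfig())
        assert list(kept.ions["rt"]) == [0.5, 5.0]

    def test_empty_block_passes_through(self):
        block = tiny_block(np.ones((3, 0)).reshape(3, 0), rts=[])
        assert m.restrict_rt(block, m.FilterConfig()).n_ions == 0

    def test_identity_when_all_inside(self):
        block = tiny_block(np.ones((3, 3)), rts=[1.0, 2.0, 3.0])
        assert m.restrict_rt(block, m.FilterConfig()).ion_ids == block.ion_ids


class TestIntensityFilter:
    def test_single_organ_above_threshold_keeps_ion(self):
        organs = ["leaf"] * 2 + ["stem_bark"] * 2 + ["fruit"] * 2
        X = np.array([[2500, 1999], [2500, 1999],
                      [50, 1999], [50, 1999], [50, 1999], [50, 1999]], dtype=float)
        block = tiny_block(X, rts=[1, 2])
        kept = m.filter_by_intensity(block, meta(organs), m.FilterConfig())
        assert kept.ion_ids == [block.ion_ids[0]]  # strict >2000 drops the 1999 ion

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        organs = np.repeat(["leaf", "stem_bark", "fruit"], 6)
        X = rng.lognormal(mean=7.6, sigma=1.0, size=(18, 40))
        block = tiny_block(X, rts=np.linspace(1, 4, 40))
        kept = m.filter_by_intensity(block, meta(list(organs)), m.FilterConfig())
        expected = brute_force_intensity_filter(X, organs, 2000.0)
        assert kept.ion_ids == [block.ion_ids[j] for j in expected]

    def test_unknown_organ_label_is_data_error(self):
        block = tiny_block(np.ones((2, 1)), rts=[1])
        with pytest.raises(FeatureError, match="organ"):
            m.filter_by_intensity(block, meta(["leaf", "root"]), m.FilterConfig())

    def test_raising_threshold_never_keeps_more(self):
        rng = np.random.default_rng(1)
        organs = list(np.repeat(["leaf", "stem_bark", "fruit"], 4))
        X = rng.lognormal(7.5, 1.2, size=(12, 30))
        block = tiny_block(X, rts=np.linspace(1, 4, 30))
        counts = [
            m.filter_by_intensity(block, meta(organs),
                                  m.FilterConfig(intensity_threshold=thr)).n_ions
            for thr in (500, 1000, 2000, 4000, 8000)]
        assert counts == sorted(counts, reverse=True)


class TestPruneCorrelated:
    def test_planted_clones_removed_parent_kept(self, default_dataset):
        d = default_dataset
        cfg = m.FilterConfig()
        for block in (d["neg"], d["pos"]):
            pruned, log = m.prune_correlated(block, cfg)
            pairs = [(p, c) for p, c in d["gt"].redundant_pairs
                     if p in block.intensities.columns]
            removed = set(log["removed"])
            for parent, clone in pairs:
                assert clone in removed
                assert parent in pruned.intensities.columns

    def test_matches_brute_force_on_small_instances(self):
        rng = np.random.default_rng(2)
        for trial in range(5):
            n_ions = 30
            X = rng.lognormal(8, 1, size=(20, n_ions))
            # clusters of shared RT to force nontrivial groups
            rts = rng.choice(np.linspace(1, 3, 8), size=n_ions)
            # plant a few correlated pairs at shared RT
            for j in range(0, 6, 2):
                X[:, j + 1] = X[:, j] * (1 + rng.normal(0, 0.02, size=20))
                rts[j + 1] = rts[j]
            block = tiny_block(X, rts=rts)
            cfg = m.FilterConfig(rt_tolerance=0.02, r_threshold=0.8)
            pruned, _ = m.prune_correlated(block, cfg)
            expected = brute_force_prune(X, rts, 0.8, 0.02, block.ion_ids)
            assert pruned.ion_ids == expected

    def test_r_threshold_is_inclusive(self):
        # construct two ions with r exactly 0.8 at identical RT
        x = np.array([0.0, 1.0, 2.0, 3.0])
        # choose b such that corr(a, b) == 0.8 exactly: mix x with its reverse
        a = x
        v = x - x.mean()
        u = v / np.linalg.norm(v)
        w = np.array([1.0, -1.0, 1.0, -1.0])
        w -= w.mean()
        w -= (w @ u) * u
        w /= np.linalg.norm(w)
        b = 0.8 * u + 0.6 * w
        r = np.corrcoef(a, b)[0, 1]
        assert r == pytest.approx(0.8, abs=1e-12)
        X = np.column_stack([a + 10, b + 10])  # keep areas non-negative
        block = tiny_block(X, rts=[2.0, 2.0])
        pruned, log = m.prune_correlated(block, m.FilterConfig())
        assert pruned.n_ions == 1 and len(log) == 1

    def test_rt_gating_keeps_distant_correlated_ions(self):
        rng = np.random.default_rng(3)
        a = rng.lognormal(8, 1, 20)
        X = np.column_stack([a, a * 1.01])
        block = tiny_block(X, rts=[1.0, 1.5])
        pruned, log = m.prune_correlated(block, m.FilterConfig(rt_tolerance=0.02))
        assert pruned.n_ions == 2 and log.empty

    def test_constant_ion_not_an_error(self):
        X = np.column_stack([np.full(10, 5.0), np.arange(10, dtype=float)])
        block = tiny_block(X, rts=[1.0, 1.0])
        pruned, log = m.prune_correlated(block, m.FilterConfig())
        assert pruned.n_ions == 2
        assert log.attrs.get("constant_ions") == [block.ion_ids[0]]

    def test_never_removes_partnerless_ion(self):
        rng = np.random.default_rng(4)
        X = rng.lognormal(8, 1, size=(15, 25))
        rts = rng.uniform(0.5, 5, size=25)
        block = tiny_block(X, rts=rts)
        cfg = m.FilterConfig()
        _, log = m.prune_correlated(block, cfg)
        rt = block.ions["rt"].to_numpy()
        corr = np.corrcoef(X.T)
        for removed in log["removed"]:
            j = block.ion_ids.index(removed)
            partners = [i for i in range(25) if i != j
                        and abs(rt[i] - rt[j]) <= cfg.rt_tolerance
                        and corr[i, j] >= cfg.r_threshold]
            assert partners


class TestAssembleBlocks:
    def test_default_synthetic_counts_near_study_matrix(self, default_fit):
        # post-filter ion counts within +-15% of 198 (neg) and 160 (pos)
        neg_n = default_fit["neg_f"].n_ions
        pos_n = default_fit["pos_f"].n_ions
        assert abs(neg_n - 198) / 198 <= 0.15
        assert abs(pos_n - 160) / 160 <= 0.15

    def test_idempotence_of_filter_chain(self, default_fit):
        design = default_fit["design"]
        neg_f, pos_f = default_fit["neg_f"], default_fit["pos_f"]
        neg_2, pos_2, _ = m.assemble_blocks(neg_f, pos_f, design)
        assert neg_2.ion_ids == neg_f.ion_ids
        assert pos_2.ion_ids == pos_f.ion_ids
        pd.testing.assert_frame_equal(neg_2.intensities, neg_f.intensities)

    def test_order_sensitivity_audit(self, default_dataset):
        # pruning before vs after the intensity filter: report the difference
        d = default_dataset
        cfg = m.FilterConfig()
        a = m.restrict_rt(d["neg"], cfg)
        std, _ = m.prune_correlated(m.filter_by_intensity(a, d["design"], cfg), cfg)
        alt = m.filter_by_intensity(m.prune_correlated(a, cfg)[0], d["design"], cfg)
        diff = set(std.ion_ids) ^ set(alt.ion_ids)
        # orders may legitimately disagree only on ions near both thresholds
        assert len(diff) <= 0.1 * std.n_ions

    def test_sample_order_mismatch_is_alignment_error(self, default_dataset):
        d = default_dataset
        shuffled = d["design"].iloc[::-1].reset_index(drop=True)
        with pytest.raises(AlignmentError):
            m.assemble_blocks(d["neg"], d["pos"], shuffled)

    def test_roundtrip_csv_preserves_block(self, default_dataset, tmp_path):
        block = default_dataset["neg"]
        block.to_csv(tmp_path / "b.csv")
        back = m.FeatureBlock.from_csv(tmp_path / "b.csv", "neg")
        assert back.ion_ids == block.ion_ids
        assert np.allclose(back.values(), block.values())
        assert np.allclose(back.ions["rt"], block.ions["rt"])
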