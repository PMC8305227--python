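import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cernet.circuits import find_motifs, rank_motifs, threshold_sweep
from cernet.corr import pearson_pairs
from cernet.io import CernetError, make_interaction_table

from conftest import make_matrix


def brute_force_motifs(mi, lnc, m, threshold, interactions=None,
                       require_evidence=False, p_max=None):
    """Exhaustive triple scan over raw expression vectors (oracle)."""

    def r_of(x, y):
        x, y = np.asarray(x, float), np.asarray(y, float)
        if x.std() == 0 or y.std() == 0:
            return np.nan
        return np.corrcoef(x, y)[0, 1]

    supported = set()
    if interactions is not None:
        sub = interactions[interactions["flag"] == 1]
        supported = set(zip(sub["mirna_id"], sub["partner_id"]))

    found = set()
    for mi_id, lnc_id, m_id in itertools.product(
        mi.feature_ids, lnc.feature_ids, m.feature_ids
    ):
        r1 = r_of(mi.values.loc[mi_id], lnc.values.loc[lnc_id])
        r2 = r_of(mi.values.loc[mi_id], m.values.loc[m_id])
        r3 = r_of(lnc.values.loc[lnc_id], m.values.loc[m_id])
        if np.isnan(r1) or np.isnan(r2) or np.isnan(r3):
            continue
        if not (r1 <= -threshold and r1 < 0 and r2 <= -threshold and r2 < 0
                and r3 >= threshold and r3 > 0):
            continue
        if p_max is not None:
            from cernet.corr import correlation_pvalue

            n = mi.n_samples
            if max(correlation_pvalue(r1, n), correlation_pvalue(r2, n),
                   correlation_pvalue(r3, n)) > p_max:
                continue
        if require_evidence and not (
            (mi_id, m_id) in supported and (mi_id, lnc_id) in supported
        ):
            continue
        found.add((lnc_id, mi_id, m_id))
    return found


def pair_tables(mi, lnc, m):
    return (
        pearson_pairs(mi, lnc),
        pearson_pairs(mi, m),
        pearson_pairs(lnc, m),
    )


def toy_interactions(mi, lnc, m, rng, density=0.5):
    rows = []
    for mi_id in mi.feature_ids:
        for partner, cls, src in [
            *[(p, "mRNA", "TarBase") for p in m.feature_ids],
            *[(p, "lncRNA", "miRcode") for p in lnc.feature_ids],
        ]:
            rows.append({"mirna_id": mi_id, "partner_id": partner,
                         "partner_class": cls, "source": src,
                         "flag": int(rng.random() < density)})
    return make_interaction_table(pd.DataFrame(rows))


class TestFindMotifs:
    @pytest.mark.parametrize("threshold", [0.0, 0.1, 0.3])
    def test_equals_exhaustive_enumeration(self, rng, threshold):
        """Merge-based enumeration equals the brute-force triple scan."""
        mi = make_matrix(rng.standard_normal((8, 25)), "miRNA", prefix="MI")
        lnc = make_matrix(rng.standard_normal((7, 25)), "lncRNA", prefix="LNC")
        m = make_matrix(rng.standard_normal((9, 25)), "mRNA", prefix="M")
        inter = toy_interactions(mi, lnc, m, rng)
        for require in (False, True):
            got = find_motifs(*pair_tables(mi, lnc, m), interactions=inter,
                              threshold=threshold, require_evidence=require)
            expected = brute_force_motifs(mi, lnc, m, threshold, inter,
                                          require_evidence=require)
            assert {(x.lncrna, x.mirna, x.mrna) for x in got} == expected

    def test_all_positive_triple_never_emitted(self, rng):
        z = rng.standard_normal(30)
        mi = make_matrix((z + 0.1 * rng.standard_normal((1, 30))), "miRNA", prefix="MI")
        lnc = make_matrix((z + 0.1 * rng.standard_normal((1, 30))), "lncRNA", prefix="LNC")
        m = make_matrix((z + 0.1 * rng.standard_normal((1, 30))), "mRNA", prefix="M")
        assert find_motifs(*pair_tables(mi, lnc, m), threshold=0.0) == []

    def test_p_max_filters_all_three_edges(self, small_matrices):
        mi, lnc, m = small_matrices
        loose = find_motifs(*pair_tables(mi, lnc, m), threshold=0.0, p_max=1.0)
        tight = find_motifs(*pair_tables(mi, lnc, m), threshold=0.0, p_max=1e-12)
        assert len(tight) <= len(loose)
        assert tight == []

    def test_unknown_anchor_is_named_in_error(self, small_matrices):
        mi, lnc, m = small_matrices
        with pytest.raises(CernetError, match="NOPE"):
            find_motifs(*pair_tables(mi, lnc, m), threshold=0.2, anchor="NOPE")

    def test_negative_threshold_rejected(self, small_matrices):
        mi, lnc, m = small_matrices
        with pytest.raises(CernetError, match="threshold"):
            find_motifs(*pair_tables(mi, lnc, m), threshold=-0.1)

    def test_anchor_restricts_output(self, rng):
        mi = make_matrix(rng.standard_normal((5, 25)), "miRNA", prefix="MI")
        lnc = make_matrix(rng.standard_normal((5, 25)), "lncRNA", prefix="LNC")
        m = make_matrix(rng.standard_normal((5, 25)), "mRNA", prefix="M")
        all_motifs = find_motifs(*pair_tables(mi, lnc, m), threshold=0.0)
        if all_motifs:
            anchor = all_motifs[0].mirna
            anchored = find_motifs(*pair_tables(mi, lnc, m), threshold=0.0,
                                   anchor=anchor)
            assert anchored
            assert all(anchor in (x.lncrna, x.mirna, x.mrna) for x in anchored)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000), threshold=st.floats(0.0, 0.9))
    def test_sign_pattern_always_holds(self, seed, threshold):
        rng = np.random.default_rng(seed)
        mi = make_matrix(rng.standard_normal((4, 12)), "miRNA", prefix="MI")
        lnc = make_matrix(rng.standard_normal((4, 12)), "lncRNA", prefix="LNC")
        m = make_matrix(rng.standard_normal((4, 12)), "mRNA", prefix="M")
        for motif in find_motifs(*pair_tables(mi, lnc, m), threshold=threshold):
            assert motif.r_mi_lnc < 0 and motif.r_mi_m < 0 and motif.r_lnc_m > 0
            assert motif.weakest_edge >= threshold


class TestThresholdSweep:
    def test_counts_monotone_and_gated_below_ungated(self, rng):
        mi = make_matrix(rng.standard_normal((6, 20)), "miRNA", prefix="MI")
        lnc = make_matrix(rng.standard_normal((6, 20)), "lncRNA", prefix="LNC")
        m = make_matrix(rng.standard_normal((6, 20)), "mRNA", prefix="M")
        inter = toy_interactions(mi, lnc, m, rng)
        sweep = threshold_sweep(*pair_tables(mi, lnc, m), inter,
                                thresholds=[0.0, 0.2, 0.4, 0.6])
        counts = sweep["n_motifs"].to_numpy()
        gated = sweep["n_evidence_gated"].to_numpy()
        assert (np.diff(counts) <= 0).all()
        assert (np.diff(gated) <= 0).all()
        assert (gated <= counts).all()

    def test_empty_interactions_give_zero_gated(self, small_matrices):
        mi, lnc, m = small_matrices
        sweep = threshold_sweep(*pair_tables(mi, lnc, m), None, [0.0, 0.3])
        assert (sweep["n_evidence_gated"] == 0).all()

    def test_unsorted_thresholds_rejected(self, small_matrices):
        mi, lnc, m = small_matrices
        with pytest.raises(CernetError, match="ascending"):
            threshold_sweep(*pair_tables(mi, lnc, m), None, [0.4, 0.2])


class TestRankMotifs:
    def _motif(self, lnc, mi, m, weakest):
        from cernet.circuits import TriangleMotif

        return TriangleMotif(
            lncrna=lnc, mirna=mi, mrna=m,
            r_mi_lnc=-weakest, r_mi_m=-0.9, r_lnc_m=0.9,
            p_mi_lnc=0.01, p_mi_m=0.01, p_lnc_m=0.01,
        )

    def test_strongest_weakest_edge_first(self):
        a = self._motif("L1", "MI1", "M1", 0.65)
        b = self._motif("L2", "MI2", "M2", 0.61)
        assert rank_motifs([b, a]) == [a, b]

    def test_top_n_larger_than_count_returns_all(self):
        a = self._motif("L1", "MI1", "M1", 0.65)
        assert rank_motifs([a], top_n=10) == [a]

    def test_ties_break_lexicographically_and_order_is_permutation_invariant(self):
        motifs = [self._motif(f"L{i}", f"MI{i}", f"M{i}", 0.5) for i in range(6)]
        ref = rank_motifs(motifs)
        rng = np.random.default_rng(0)
        for _ in range(5):
            shuffled = list(rng.permutation(len(motifs)))
            assert rank_motifs([motifs[i] for i in shuffled]) == ref
        assert [m.lncrna for m in ref] == sorted(m.lncrna for m in motifs)
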