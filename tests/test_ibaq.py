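"""Digestion, iBAQ computation, differential statistics and enrichment."""

import math
import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herbnet.core import GroupDesign, IBAQTable, UsageError, ValidationError
from herbnet.ibaq import (
    compute_ibaq,
    count_theoretical_peptides,
    differential,
    enrich,
    tryptic_fragments,
)
from herbnet.core import PathwayGeneSet

AA = "ACDEFGHIKLMNPQRSTVWY"


def regex_split_oracle(seq, proline_rule, min_len=6, max_len=30):
    """Independent fragment enumeration via regex split."""
    pat = r"(?<=[KR])(?!P)" if proline_rule else r"(?<=[KR])"
    frags = [f for f in re.split(pat, seq) if f]
    return sum(min_len <= len(f) <= max_len for f in frags)


@pytest.mark.parametrize(
    "seq,proline_rule,count",
    [
        ("MKAAAAAR", True, 1),          # MK (too short) + AAAAAR
        ("AAAAKPAAAAAR", True, 1),      # Keil rule: no cut before P
        ("AAAAKPAAAAAR", False, 1),     # without the rule: AAAAK (short) + PAAAAAR
        ("KKKKKK", True, 0),            # all fragments length 1 except trailing run
        ("ACDEFG", True, 1),            # no cleavage site at all
    ],
)
def test_digest_hand_cases(seq, proline_rule, count):
    assert count_theoretical_peptides(seq, proline_rule=proline_rule) == count


def test_digest_matches_regex_and_pyteomics_oracles():
    pyteomics_parser = pytest.importorskip("pyteomics.parser")
    rng = np.random.default_rng(13)
    for _ in range(200):
        n = int(rng.integers(1, 120))
        seq = "".join(rng.choice(list(AA), size=n))
        for rule in (True, False):
            mine = count_theoretical_peptides(seq, proline_rule=rule)
            assert mine == regex_split_oracle(seq, rule)
        # positional cleavage cross-check against pyteomics on the Keil rule
        frags = [p for _, p in pyteomics_parser.xcleave(seq, r"[KR](?!P)",
                                                        missed_cleavages=0)]
        assert tryptic_fragments(seq, proline_rule=True) == frags


@settings(derandomize=True, max_examples=150)
@given(st.text(alphabet=AA + "XBZU", min_size=1, max_size=200),
       st.booleans())
def test_digest_is_length_conserving(seq, proline_rule):
    frags = tryptic_fragments(seq, proline_rule=proline_rule)
    assert "".join(frags) == seq


def test_digest_rejects_bad_bounds():
    with pytest.raises(UsageError):
        count_theoretical_peptides("MKAAAAAR", min_len=10, max_len=5)


def _matrix(values, samples):
    return pd.DataFrame(values, columns=samples)


def test_ibaq_division_and_normalisation():
    mat = pd.DataFrame({"s1": [1000.0, 3000.0]}, index=["p1", "p2"])
    table = compute_ibaq(mat, {"p1": 10, "p2": 10})
    assert table.raw.loc["p1", "s1"] == 100.0
    assert table.norm["s1"].tolist() == pytest.approx([0.25, 0.75])


def test_ibaq_zero_count_excluded_and_missing_count_error():
    mat = pd.DataFrame({"s1": [10.0, 20.0]}, index=["p1", "p2"])
    table = compute_ibaq(mat, {"p1": 2, "p2": 0})
    assert table.excluded == ("p2",)
    assert list(table.norm.index) == ["p1"]
    with pytest.raises(UsageError, match="p2"):
        compute_ibaq(mat, {"p1": 2})


def test_ibaq_dead_sample_is_hard_error():
    mat = pd.DataFrame({"s1": [0.0, 0.0]}, index=["p1", "p2"])
    with pytest.raises(ValidationError, match="s1"):
        compute_ibaq(mat, {"p1": 2, "p2": 3})


def test_ibaq_scale_equivariance_and_norm_invariance():
    rng = np.random.default_rng(8)
    mat = pd.DataFrame(rng.uniform(1, 1e6, size=(30, 4)),
                       index=[f"p{i}" for i in range(30)],
                       columns=[f"s{j}" for j in range(4)])
    counts = {f"p{i}": int(rng.integers(1, 40)) for i in range(30)}
    t1 = compute_ibaq(mat, counts)
    t2 = compute_ibaq(mat * 10.0, counts)
    assert np.allclose(t2.raw, t1.raw * 10.0)
    assert np.allclose(t2.norm, t1.norm)
    assert np.allclose(t1.norm.sum(axis=0), 1.0, atol=1e-9)


def _two_group_design(n=4):
    groups = {f"a{i}": "A" for i in range(n)} | {f"b{i}": "B" for i in range(n)}
    return GroupDesign(groups=groups)


def _ibaq_from(norm):
    return IBAQTable(raw=norm, norm=norm)


def test_differential_degenerate_identical_values():
    cols = [f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)]
    norm = pd.DataFrame([[0.5] * 6, [0.1] * 6], index=["p1", "p2"], columns=cols)
    out = differential(_ibaq_from(norm), _two_group_design(3), ("A", "B"))
    assert (out["log2fc"] == 0).all()
    assert (out["p"] == 1.0).all()


def test_differential_direction_and_symmetry():
    rng = np.random.default_rng(42)
    cols = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
    base = rng.uniform(0.1, 1.0, size=(10, 8))
    base[0, 4:] *= 4.0  # planted increase in B
    norm = pd.DataFrame(base, index=[f"p{i}" for i in range(10)], columns=cols)
    design = _two_group_design(4)
    ab = differential(_ibaq_from(norm), design, ("A", "B")).set_index("accession")
    ba = differential(_ibaq_from(norm), design, ("B", "A")).set_index("accession")
    assert ab.loc["p0", "log2fc"] > 0
    assert np.allclose(ab["log2fc"], -ba["log2fc"])
    assert np.allclose(ab["p"], ba["p"])


def test_differential_zero_handling_keeps_fc_finite():
    cols = [f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)]
    norm = pd.DataFrame(
        [[0.0, 0.0, 0.0, 0.4, 0.5, 0.45], [0.2] * 6],
        index=["p1", "p2"], columns=cols,
    )
    out = differential(_ibaq_from(norm), _two_group_design(3), ("A", "B"))
    assert np.isfinite(out["log2fc"]).all()
    assert out.set_index("accession").loc["p1", "log2fc"] > 0


def test_differential_requires_known_groups():
    cols = [f"a{i}" for i in range(3)] + [f"b{i}" for i in range(3)]
    norm = pd.DataFrame([[0.5] * 6], index=["p1"], columns=cols)
    with pytest.raises(UsageError):
        differential(_ibaq_from(norm), _two_group_design(3), ("A", "ZZ"))


def test_bh_is_monotone_in_raw_p():
    rng = np.random.default_rng(1)
    cols = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
    norm = pd.DataFrame(rng.uniform(0.1, 1, size=(50, 8)),
                        index=[f"p{i}" for i in range(50)], columns=cols)
    out = differential(_ibaq_from(norm), _two_group_design(4), ("A", "B"))
    s = out.sort_values("p")
    assert (s["fdr"].diff().dropna() >= -1e-12).all()


def comb_tail(k, N, K, n):
    return sum(math.comb(K, j) * math.comb(N - K, n - j)
               for j in range(k, min(K, n) + 1)) / math.comb(N, n)


def test_enrich_exact_cases_and_contract():
    background = {f"g{i}" for i in range(20)}
    five = {f"g{i}" for i in range(5)}
    sets = [
        PathwayGeneSet("hit", "", frozenset(five)),
        PathwayGeneSet("whole", "", frozenset(background)),
    ]
    out = enrich(five, background, sets).set_index("pathway_id")
    assert out.loc["hit", "p"] == pytest.approx(1 / math.comb(20, 5), rel=1e-12)
    assert out.loc["hit", "p"] == pytest.approx(comb_tail(5, 20, 5, 5), rel=1e-12)
    assert out.loc["whole", "p"] == pytest.approx(1.0)
    with pytest.raises(UsageError):
        enrich({"g0"}, set(), sets)
    with pytest.raises(UsageError):
        enrich({"zz"}, background, sets)


def test_enrich_via_mapping_collapses_isoforms():
    background = {"acc1", "acc2", "acc3"}
    mapping = pd.DataFrame(
        [("gA", "acc1"), ("gA", "acc2"), ("gB", "acc3")],
        columns=["target_id", "accession"],
    )
    sets = [PathwayGeneSet("s", "", frozenset({"gA"}))]
    out = enrich({"acc2"}, background, sets, mapping=mapping)
    row = out.iloc[0]
    assert (row["k"], row["K"], row["N"], row["n"]) == (1, 1, 2, 1)
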