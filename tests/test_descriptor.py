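"""Descriptor computation, rare codes and the linear endpoint model."""

import numpy as np
import pytest

import quasicw as q


def test_rare_codes_under_published_split1(thp1_records):
    """Element codes never appearing in an active-training row are rare
    at T=1; ubiquitous codes never are."""
    active = [r for r in thp1_records if r.set_label == "A"]
    universe = set()
    for r in thp1_records:
        universe.update(q.tokenize(r.quasi_smiles))
    rare = q.mark_rare_codes(active, T=1, alphabet=universe)
    assert {"[Ge]", "[Hf]", "[Ti]", "[Cr]", "[Er]", "[Sb]"} <= rare
    assert "O" not in rare
    assert "[c25,00]" not in rare


def test_threshold_boundary_one_occurrence_is_not_rare():
    recs = [
        q.QuasiSmilesRecord(id=1, quasi_smiles="[Zn]=O", endpoint=1.0),
        q.QuasiSmilesRecord(id=2, quasi_smiles="O=O", endpoint=2.0),
    ]
    rare = q.mark_rare_codes(recs, T=1)
    assert "[Zn]" not in rare
    rare2 = q.mark_rare_codes(recs, T=2)
    assert "[Zn]" in rare2 and "O" not in rare2


def test_mark_rare_rejects_empty_active_set():
    with pytest.raises(ValueError):
        q.mark_rare_codes([], T=1)


def test_compute_dcw_hand_example():
    wt = q.WeightTable(weights={"O": 1.0, "=": 1.0, "[Al]": 2.0, "[c25,00]": 3.0})
    codes = q.tokenize("O=[Al]O[Al]=O[c25,00]")
    assert q.compute_dcw(codes, wt) == pytest.approx(12.0)


def test_compute_dcw_rare_and_unknown_codes_contribute_zero():
    wt = q.WeightTable(weights={"O": 1.0, "[Ge]": 5.0}, rare_codes={"[Ge]"})
    assert q.compute_dcw(q.tokenize("O=[Ge]=O[c25,00]"), wt) == pytest.approx(2.0)


def test_dcw_is_order_insensitive():
    wt = q.WeightTable(weights={"O": 0.7, "=": -0.3, "[Co]": 1.1})
    a = q.compute_dcw(q.tokenize("O=[Co]"), wt)
    b = q.compute_dcw(q.tokenize("[Co]=O"), wt)
    assert a == pytest.approx(b)


def test_rare_element_records_share_printed_calculated_values(thp1_df):
    """Ge, Hf and Ti dioxides have no active-training rows, so the
    published model assigns them identical calculated viability at each
    concentration — the rare-code degeneracy."""
    skel = thp1_df.quasi_smiles.str.replace(r"\[c\d+,00\]$", "", regex=True)
    conc = thp1_df.quasi_smiles.str.extract(r"(\[c\d+,00\])$")[0]
    pivot = thp1_df.assign(skel=skel, conc=conc).pivot(
        index="skel", columns="conc", values="calculated"
    )
    for code in ("[Ge]", "[Hf]", "[Ti]"):
        row = pivot.loc[f"O={code}=O"]
        assert np.allclose(row.values, pivot.loc["O=[Ge]=O"].values)


def test_concentration_offsets_constant_in_printed_model(thp1_df):
    """The published calculated column differs between two concentrations
    by a skeleton-independent constant — the additive-model signature."""
    skel = thp1_df.quasi_smiles.str.replace(r"\[c\d+,00\]$", "", regex=True)
    conc = thp1_df.quasi_smiles.str.extract(r"(\[c\d+,00\])$")[0]
    pivot = thp1_df.assign(skel=skel, conc=conc).pivot(
        index="skel", columns="conc", values="calculated"
    )
    for a, b, expected in [
        ("[c25,00]", "[c50,00]", 7.4087),
        ("[c50,00]", "[c100,00]", 10.6735),
        ("[c100,00]", "[c200,00]", 6.3279),
    ]:
        diff = pivot[a] - pivot[b]
        assert diff.max() - diff.min() < 0.001
        assert diff.mean() == pytest.approx(expected, abs=0.001)


def test_fit_linear_recovers_exact_line():
    x = np.array([0.0, 1.0, 2.0, 3.0])
    model = q.fit_linear(x, 2 * x + 5)
    assert model.c0 == pytest.approx(5.0)
    assert model.c1 == pytest.approx(2.0)


def test_fit_linear_degenerate_descriptor_raises():
    with pytest.raises(q.DegenerateModelError):
        q.fit_linear([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def test_predict_with_zero_weights_gives_intercept():
    wt = q.WeightTable(weights={"O": 0.0, "=": 0.0})
    model = q.LinearModel(c0=42.0, c1=3.0)
    rec = q.QuasiSmilesRecord(id=1, quasi_smiles="O=O", endpoint=0.0)
    assert q.predict(rec, wt, model) == pytest.approx(42.0)


def test_condition_code_swap_shifts_prediction_by_constant():
    """Two records differing only in the condition code differ in
    prediction by c1 * (w_condA - w_condB), independent of skeleton."""
    wt = q.WeightTable(
        weights={"O": 0.5, "=": -0.1, "[Al]": 1.0, "[Zn]": -2.0,
                 "[c25,00]": 2.0, "[c50,00]": 1.2}
    )
    model = q.LinearModel(c0=10.0, c1=4.0)
    expected = model.c1 * (wt.weight("[c25,00]") - wt.weight("[c50,00]"))
    for skel in ("O=[Al]O[Al]=O", "[Zn]=O"):
        lo = q.QuasiSmilesRecord(id=1, quasi_smiles=skel + "[c25,00]", endpoint=0)
        hi = q.QuasiSmilesRecord(id=2, quasi_smiles=skel + "[c50,00]", endpoint=0)
        assert q.predict(lo, wt, model) - q.predict(hi, wt, model) == pytest.approx(
            expected
        )


def test_build_weight_table_zeroes_rare_codes(thp1_records, split1):
    wt = q.build_weight_table(thp1_records, split1.ids("A"), T=1)
    assert all(wt.weights[c] == 0.0 for c in wt.rare_codes)
    assert all(wt.weights[c] == 1.0 for c in wt.active_codes)
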