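"""Reading and harmonising summary-statistic tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adipomr.sumstats import (
    ConfigurationError,
    EmptyInputError,
    EmptyOverlapError,
    VariantAssociation,
    harmonise,
    is_palindromic,
    read_summary_stats,
)

HEADER = "variant_id\teffect_allele\tother_allele\teaf\tbeta\tse\tpvalue"
ROWS = [
    "rs1\tA\tG\t0.30\t0.05\t0.006\t1e-12",
    "rs2\tC\tT\t0.62\t-0.04\t0.005\t1e-10",
    "rs3\tG\tA\t0.11\t0.03\t0.004\t1e-9",
]


def write_table(path, rows=ROWS, header=HEADER, sep="\t"):
    text = "\n".join([header] + list(rows)) + "\n"
    path.write_text(text.replace("\t", sep))
    return path


@pytest.mark.parametrize("sep", ["\t", ","], ids=["tsv", "csv"])
def test_read_well_formed_table(tmp_path, sep):
    """Both delimiters yield the same three records, no diagnostics."""
    records, diags = read_summary_stats(write_table(tmp_path / "t", sep=sep))
    assert len(records) == 3 and diags == []
    assert [r.variant_id for r in records] == ["rs1", "rs2", "rs3"]
    assert records[1] == VariantAssociation("rs2", "C", "T", -0.04, 0.005, 0.62, 1e-10)


@pytest.mark.parametrize(
    "bad_row, reason",
    [
        ("rsX\tA\tG\t0.3\t0.05\t0\t0.5", "non-positive SE"),
        ("rsX\tA\tG\t0.3\t0.05\t-0.1\t0.5", "non-positive SE"),
        ("rsX\tA\tG\t0.3\tNA\t0.01\t0.5", "non-numeric beta or SE"),
        ("rsX\tA\tA\t0.3\t0.05\t0.01\t0.5", "invalid alleles"),
        ("rsX\tI\tD\t0.3\t0.05\t0.01\t0.5", "invalid alleles"),
    ],
)
def test_read_rejects_bad_rows_with_diagnostics(tmp_path, bad_row, reason):
    records, diags = read_summary_stats(
        write_table(tmp_path / "t", rows=ROWS + [bad_row])
    )
    assert len(records) == 3
    assert diags == [(3, reason)]


def test_read_missing_mapped_column_names_it(tmp_path):
    with pytest.raises(ConfigurationError, match="snp_col"):
        read_summary_stats(
            write_table(tmp_path / "t"), column_map={"variant_id": "snp_col"}
        )


def test_read_zero_valid_rows_raises(tmp_path):
    path = write_table(tmp_path / "t", rows=["rs1\tA\tG\t0.3\tx\t0\t0.5"])
    with pytest.raises(EmptyInputError):
        read_summary_stats(path)


def va(vid, ea, oa, beta, se=0.01, eaf=None):
    return VariantAssociation(vid, ea, oa, beta, se, eaf)


def test_harmonise_identity_retained_unchanged():
    data = harmonise([va("rs1", "A", "G", 0.05)], [va("rs1", "A", "G", 0.10)])
    assert data.n_variants == 1 and data.dropped == []
    assert data.gamma[0] == 0.05 and data.Gamma[0] == 0.10


def test_harmonise_allele_swap_flips_outcome_sign():
    data = harmonise(
        [va("rs1", "A", "G", 0.05)], [va("rs1", "G", "A", 0.10, eaf=0.3)]
    )
    assert data.Gamma[0] == -0.10


def test_harmonise_strand_complement_matches():
    # exposure A/G vs outcome T/C: same variant on the opposite strand
    same = harmonise([va("rs1", "A", "G", 0.05)], [va("rs1", "T", "C", 0.10)])
    assert same.Gamma[0] == 0.10
    flipped = harmonise([va("rs1", "A", "G", 0.05)], [va("rs1", "C", "T", 0.10)])
    assert flipped.Gamma[0] == -0.10


def test_harmonise_irreconcilable_alleles_dropped_not_raised():
    data = harmonise([va("rs1", "A", "G", 0.05)], [va("rs1", "A", "C", 0.10)])
    assert data.n_variants == 0
    assert data.dropped == [("rs1", "allele mismatch")]


@pytest.mark.parametrize(
    "policy, out_eaf, expect_kept, expect_reason",
    [
        ("drop", 0.2, False, "palindromic"),
        ("infer_by_eaf", 0.50, False, "palindromic, ambiguous frequency"),
        ("infer_by_eaf", 0.55, False, "palindromic, ambiguous frequency"),
        ("infer_by_eaf", 0.2, True, None),
        ("infer_by_eaf", None, False, "palindromic, missing frequency"),
    ],
)
def test_palindromic_policies(policy, out_eaf, expect_kept, expect_reason):
    data = harmonise(
        [va("rs1", "A", "T", 0.05, eaf=0.2)],
        [va("rs1", "A", "T", 0.10, eaf=out_eaf)],
        palindrome_policy=policy,
        eaf_window=0.08,
    )
    if expect_kept:
        assert data.n_variants == 1 and data.Gamma[0] == 0.10
    else:
        assert data.dropped == [("rs1", expect_reason)]


def test_palindromic_opposite_frequency_flips_sign():
    data = harmonise(
        [va("rs1", "A", "T", 0.05, eaf=0.2)],
        [va("rs1", "A", "T", 0.10, eaf=0.8)],
        palindrome_policy="infer_by_eaf",
    )
    assert data.Gamma[0] == -0.10


def test_zero_exposure_effect_dropped():
    data = harmonise([va("rs1", "A", "G", 0.0)], [va("rs1", "A", "G", 0.10)])
    assert data.dropped == [("rs1", "zero exposure effect")]


def test_empty_overlap_raises():
    with pytest.raises(EmptyOverlapError):
        harmonise([va("rs1", "A", "G", 0.05)], [va("rs2", "A", "G", 0.10)])


def test_round_trip_self_harmonisation():
    """harmonise(x, x) keeps every non-palindromic variant with Gamma=beta."""
    table = [
        va("rs1", "A", "G", 0.05),
        va("rs2", "C", "T", -0.04),
        va("rs3", "A", "T", 0.03),  # palindromic, dropped under default policy
    ]
    data = harmonise(table, table)
    assert data.variant_id.tolist() == ["rs1", "rs2"]
    assert np.array_equal(data.Gamma, data.gamma)
    assert data.dropped == [("rs3", "palindromic")]


def test_sign_flip_involution():
    """Swapping outcome alleles and negating betas is a no-op after harmonisation."""
    exposure = [va("rs1", "A", "G", 0.05), va("rs2", "C", "T", -0.04)]
    outcome = [va("rs1", "A", "G", 0.10, eaf=0.3), va("rs2", "C", "T", 0.07, eaf=0.6)]
    swapped = [
        VariantAssociation(
            v.variant_id, v.other_allele, v.effect_allele, -v.beta, v.se,
            None if v.eaf is None else 1 - v.eaf,
        )
        for v in outcome
    ]
    a = harmonise(exposure, outcome)
    b = harmonise(exposure, swapped)
    assert np.array_equal(a.Gamma, b.Gamma)
    assert a.variant_id.tolist() == b.variant_id.tolist()


alleles = st.sampled_from("ACGT")
variant_ids = st.integers(0, 19).map(lambda i: f"rs{i}")


@st.composite
def associations(draw):
    ea = draw(alleles)
    oa = draw(alleles.filter(lambda a: True))
    if ea == oa:
        oa = {"A": "C", "C": "A", "G": "T", "T": "G"}[ea]
    return VariantAssociation(
        draw(variant_ids), ea, oa,
        beta=draw(st.floats(-1, 1, allow_nan=False)),
        se=draw(st.floats(0.001, 1)),
        eaf=draw(st.one_of(st.none(), st.floats(0.01, 0.99))),
    )


def dedupe(items):
    seen, out = set(), []
    for v in items:
        if v.variant_id not in seen:
            seen.add(v.variant_id)
            out.append(v)
    return out


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    st.lists(associations(), min_size=1, max_size=20).map(dedupe),
    st.lists(associations(), min_size=1, max_size=20).map(dedupe),
    st.sampled_from(["drop", "infer_by_eaf"]),
)
def test_count_conservation(exposure, outcome, policy):
    """|records| + |dropped| equals the size of the ID intersection."""
    shared = {v.variant_id for v in exposure} & {v.variant_id for v in outcome}
    try:
        data = harmonise(exposure, outcome, palindrome_policy=policy)
    except EmptyOverlapError:
        assert not shared
        return
    assert data.n_variants + len(data.dropped) == len(shared)
    assert len(set(data.variant_id.tolist())) == data.n_variants
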