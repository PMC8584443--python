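"""Feature pipeline: conical coordinates, composition vectors, sequence codes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepcaps.constants import AMINO_ACIDS, CLASS_OF, MOLECULAR_WEIGHT
from pepcaps.features import (
    AAC_DIM,
    BIO_DIM,
    DPC_DIM,
    RCC_DIM,
    Peptide,
    SequenceError,
    aac,
    build_bio_feature,
    classify_residue,
    conical_map,
    conical_params,
    dpc,
    encode_sequence,
    geometric_centers,
    moment_features,
    rcc_feature,
    standardize_properties,
)

peptide_strings = st.text(alphabet=AMINO_ACIDS, min_size=2, max_size=50)


# ---------------------------------------------------------------------------
# residue classes and peptide validation


@pytest.mark.parametrize(
    "residue,cls",
    [("A", 1), ("W", 1), ("G", 2), ("Q", 2), ("K", 3), ("H", 3), ("D", 4), ("E", 4)],
)
def test_residue_classification(residue, cls):
    """The four polarity classes partition the alphabet as published."""
    assert classify_residue(residue) == cls


def test_residue_classes_partition_alphabet():
    assert sorted(AMINO_ACIDS) == sorted(a for a in AMINO_ACIDS)
    assert {classify_residue(a) for a in AMINO_ACIDS} == {1, 2, 3, 4}


@pytest.mark.parametrize("bad", ["AX", "B", "AUG", "A"])
def test_invalid_peptides_rejected(bad):
    with pytest.raises(SequenceError):
        Peptide(bad)


def test_classify_rejects_non_canonical():
    with pytest.raises(SequenceError):
        classify_residue("X")


# ---------------------------------------------------------------------------
# property standardization


def test_standardize_zero_variance_column_named():
    raw = np.random.default_rng(0).normal(0, 1, (20, 100))
    raw[:, 7] = 3.14
    with pytest.raises(ValueError, match="p7"):
        standardize_properties(raw)


def test_standardize_columns_zero_mean_unit_sd(random_table):
    assert np.allclose(random_table.values.mean(axis=0), 0, atol=1e-9)
    assert np.allclose(random_table.values.std(axis=0), 1, atol=1e-9)


def test_standardize_idempotent(random_table):
    again = standardize_properties(random_table.values)
    assert np.allclose(again.values, random_table.values, atol=1e-12)


def test_groups_are_blocks_of_ten(random_table):
    assert random_table.n_groups == 10
    assert all(len(g) == 10 for g in random_table.groups)
    flat = [i for g in random_table.groups for i in g]
    assert sorted(flat) == list(range(100))


# ---------------------------------------------------------------------------
# conical mapping


def test_conical_angles_in_range(random_peptides, random_table):
    for pep in random_peptides:
        for g in range(10):
            params = conical_params(pep, random_table.group_values(g))
            assert all(0 <= phi <= math.pi for phi in params.phi.values())
            assert np.all((params.theta >= 0) & (params.theta <= 2 * math.pi))


def test_single_class_peptide_degenerate_angles(random_table):
    """All-alanine chains put every residue at theta = pi, phi = pi/2."""
    params = conical_params(Peptide("AAAA"), random_table.group_values(0))
    assert params.phi == {1: pytest.approx(math.pi / 2)}
    assert np.allclose(params.theta, math.pi)


def test_conical_params_match_brute_force(random_table):
    """phi/theta agree with a straight-line recomputation of the formulas."""
    pep = Peptide("AKD")  # classes 1, 3, 4
    gv = random_table.group_values(2)
    params = conical_params(pep, gv)

    sums = {a: gv[AMINO_ACIDS.index(a)].sum() for a in "AKD"}
    dbar = dict(sums)  # one residue per class here
    vals = np.array([dbar[a] for a in "AKD"])
    mu, sigma = vals.mean(), vals.std()
    for a, cls in zip("AKD", (1, 3, 4)):
        expected_phi = math.pi * abs(math.sin((dbar[a] - mu) / sigma))
        assert params.phi[cls] == pytest.approx(expected_phi, rel=1e-10)
    # single-residue classes: zero within-class deviation -> theta = pi
    assert np.allclose(params.theta, math.pi)


def test_conical_params_theta_brute_force_multimember(random_table):
    """theta for a 2-member class follows pi + 2*atan(dev/rms)."""
    pep = Peptide("AVK")  # A,V class 1; K class 3
    gv = random_table.group_values(0)
    params = conical_params(pep, gv)
    sA = gv[AMINO_ACIDS.index("A")].sum()
    sV = gv[AMINO_ACIDS.index("V")].sum()
    dbar1 = (sA + sV) / 2
    rms = math.sqrt(((sA - dbar1) ** 2 + (sV - dbar1) ** 2) / 2)
    assert params.theta[0] == pytest.approx(math.pi + 2 * math.atan((sA - dbar1) / rms))
    assert params.theta[1] == pytest.approx(math.pi + 2 * math.atan((sV - dbar1) / rms))
    assert params.theta[2] == pytest.approx(math.pi)  # singleton class


def test_spherical_identity(random_peptides, random_table):
    """Every mapped point sits on the sphere of its molecular-weight radius."""
    for pep in random_peptides:
        params = conical_params(pep, random_table.group_values(0))
        pts = conical_map(pep, params)
        norms = np.linalg.norm(pts, axis=1)
        assert np.allclose(norms, params.r, rtol=1e-8)


def test_conical_map_axis_case():
    """(r, phi, theta) = (89.09, pi/2, pi) maps to (-r, 0, 0)."""
    from pepcaps.features import ConicalParams

    pep = Peptide("AA")
    params = ConicalParams(
        phi={1: math.pi / 2},
        theta=np.array([math.pi, math.pi]),
        r=np.array([MOLECULAR_WEIGHT["A"]] * 2),
        classes=np.array([1, 1]),
    )
    pts = conical_map(pep, params)
    assert np.allclose(pts, [[-89.09, 0, 0], [-89.09, 0, 0]], atol=1e-6)


def test_conical_map_pole_case():
    from pepcaps.features import ConicalParams

    pep = Peptide("GG")
    params = ConicalParams(
        phi={2: 0.0},
        theta=np.array([1.0, 2.0]),
        r=np.array([MOLECULAR_WEIGHT["G"]] * 2),
        classes=np.array([2, 2]),
    )
    pts = conical_map(pep, params)
    assert np.allclose(pts, [[0, 0, 75.07], [0, 0, 75.07]], atol=1e-10)


# ---------------------------------------------------------------------------
# centers and moments


def test_geometric_centers_arithmetic_oracle():
    coords = np.array(
        [[1.0, 2, 3], [3, 2, 1], [0, 0, 6], [2, 2, 2], [4, 4, 4]], dtype=float
    )
    classes = np.array([1, 1, 1, 3, 3])
    u, ui = geometric_centers(coords, classes)
    assert np.allclose(u, coords.mean(axis=0))
    assert np.allclose(ui[0], coords[:3].mean(axis=0))
    assert np.allclose(ui[2], coords[3:].mean(axis=0))
    # absent classes inherit the overall center
    assert np.allclose(ui[1], u) and np.allclose(ui[3], u)


def test_geometric_centers_symmetry():
    p = np.array([[1.0, -2, 3]])
    coords = np.vstack([p, -p])
    u, ui = geometric_centers(coords, np.array([2, 2]))
    assert np.allclose(ui[1], [0, 0, 0])


def test_moment_features_degenerate_zero():
    u = np.array([1.0, 2, 3])
    ui = np.tile(u, (4, 1))
    assert np.allclose(moment_features(u, ui), 0)


def test_moment_features_symmetric_skew_zero():
    u = np.zeros(3)
    ui = np.array([[1.0, 0, 0], [-1, 0, 0], [1, 0, 0], [-1, 0, 0]])
    m = moment_features(u, ui)
    assert m[3] == pytest.approx(0, abs=1e-12)  # skewness on x


def test_moment_features_arithmetic_oracle():
    """Hand-built x-deviations 1,2,3,4 (uncentered) match direct formulas."""
    u = np.zeros(3)
    ui = np.zeros((4, 3))
    ui[:, 0] = [1, 2, 3, 4]
    dev = np.array([1.0, 2, 3, 4])
    var = (dev**2).mean()
    sd = math.sqrt(var)
    g = (dev**3).mean() / sd**3
    h = (dev**4).mean() / sd**4
    m = moment_features(u, ui)
    assert m[0] == pytest.approx(var)
    assert m[3] == pytest.approx(g)
    assert m[6] == pytest.approx(h)
    # printed sigma^2 kurtosis variant
    m2 = moment_features(u, ui, kurtosis_sigma2=True)
    assert m2[6] == pytest.approx((dev**4).mean() / var)


# ---------------------------------------------------------------------------
# composition features


def test_aac_examples():
    v = aac(Peptide("AAAA"))
    assert v[0] == 1.0 and v.sum() == pytest.approx(1)
    v = aac(Peptide("ACAC"))
    assert v[0] == 0.5 and v[1] == 0.5
    assert v.shape == (AAC_DIM,)


def test_dpc_examples():
    v = dpc(Peptide("AG"))
    ag = AMINO_ACIDS.index("A") * 20 + AMINO_ACIDS.index("G")
    assert v[ag] == 1.0 and v.sum() == pytest.approx(1)
    v = dpc(Peptide("AAA"))
    assert v[0] == 1.0
    assert v.shape == (DPC_DIM,)


def test_order_sensitivity():
    assert np.allclose(aac(Peptide("ACD")), aac(Peptide("DCA")))
    assert not np.allclose(dpc(Peptide("ACD")), dpc(Peptide("DCA")))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(peptide_strings)
def test_compositions_normalized(seq):
    pep = Peptide(seq)
    assert aac(pep).sum() == pytest.approx(1, abs=1e-9)
    assert dpc(pep).sum() == pytest.approx(1, abs=1e-9)


# ---------------------------------------------------------------------------
# assembled features


def test_dimension_ledger(random_peptides, random_table):
    pep = random_peptides[0]
    assert rcc_feature(pep, random_table).shape == (RCC_DIM,)
    bf = build_bio_feature(pep, random_table)
    assert bf.vector.shape == (BIO_DIM,)
    assert bf.matrix_view.shape == (33, 20)
    assert np.allclose(bf.matrix_view.ravel(), bf.vector)
    assert encode_sequence(pep).shape == (50,)


def test_rcc_group_blocks_are_24(random_peptides, random_table):
    v = rcc_feature(random_peptides[0], random_table)
    assert v.size == 10 * 24


def test_rcc_permutation_invariance(rng, random_table):
    seq = "ACDEFGHIKLMNPQRSTVWY"
    perm = "".join(rng.permutation(list(seq)))
    assert np.allclose(
        rcc_feature(Peptide(seq), random_table),
        rcc_feature(Peptide(perm), random_table),
        atol=1e-10,
    )
    assert np.allclose(aac(Peptide(seq)), aac(Peptide(perm)))


def test_bio_feature_deterministic(random_table):
    a = build_bio_feature(Peptide("ACDKLM"), random_table).vector
    b = build_bio_feature(Peptide("ACDKLM"), random_table).vector
    assert np.array_equal(a, b)


def test_encode_sequence_examples():
    code = encode_sequence(Peptide("AC"))
    assert list(code[:2]) == [1, 2] and np.all(code[2:] == 0)
    long = Peptide("A" * 60)
    assert encode_sequence(long).shape == (50,) and np.all(encode_sequence(long) == 1)
    full = Peptide("ACDEFGHIKL" * 5)
    assert np.all(encode_sequence(full) > 0)


def test_padding_is_contiguous_suffix(random_peptides):
    for pep in random_peptides:
        code = encode_sequence(pep)
        nz = np.flatnonzero(code)
        assert np.array_equal(nz, np.arange(len(nz)))


# ---------------------------------------------------------------------------
# full oracle equivalence: loop-based straight-line recomputation


def _oracle_features(seq: str, table) -> np.ndarray:
    """Independent recomputation of the full 660-value biological feature."""
    seq = seq[:50]
    out = []
    for g in range(10):
        gv = table.group_values(g)
        sums = {a: sum(gv[AMINO_ACIDS.index(a)][m] for m in range(10)) for a in set(seq)}
        classes = sorted({CLASS_OF[a] for a in seq})
        dbar = {}
        for i in classes:
            members = [sums[a] for a in seq if CLASS_OF[a] == i]
            dbar[i] = sum(members) / len(members)
        mu = sum(dbar.values()) / len(dbar)
        sigma = math.sqrt(sum((d - mu) ** 2 for d in dbar.values()) / len(dbar))
        phi = {}
        for i in classes:
            phi[i] = math.pi / 2 if sigma < 1e-12 else math.pi * abs(
                math.sin((dbar[i] - mu) / sigma)
            )
        pts = []
        for a in seq:
            i = CLASS_OF[a]
            devs = [sums[x] - dbar[i] for x in seq if CLASS_OF[x] == i]
            rms = math.sqrt(sum(d * d for d in devs) / len(devs))
            dev = sums[a] - dbar[i]
            theta = math.pi if rms < 1e-12 else math.pi + 2 * math.atan(dev / rms)
            r = MOLECULAR_WEIGHT[a]
            pts.append(
                (
                    r * math.sin(phi[i]) * math.cos(theta),
                    r * math.sin(phi[i]) * math.sin(theta),
                    r * math.cos(phi[i]),
                )
            )
        u = [sum(p[k] for p in pts) / len(pts) for k in range(3)]
        centers = []
        for i in (1, 2, 3, 4):
            cpts = [p for a, p in zip(seq, pts) if CLASS_OF[a] == i]
            centers.append(
                [sum(p[k] for p in cpts) / len(cpts) for k in range(3)] if cpts else u
            )
        block = [x for c in centers for x in c] + list(u)
        for stat in ("var", "skew", "kurt"):
            for k in range(3):
                devs = [c[k] - u[k] for c in centers]
                var = sum(d * d for d in devs) / 4
                sd = math.sqrt(var)
                if stat == "var":
                    block.append(var)
                elif sd < 1e-12:
                    block.append(0.0)
                elif stat == "skew":
                    block.append(sum(d**3 for d in devs) / 4 / sd**3)
                else:
                    block.append(sum(d**4 for d in devs) / 4 / sd**4)
        out.extend(block)
    # AAC
    for a in AMINO_ACIDS:
        out.append(seq.count(a) / len(seq))
    # DPC
    pairs = [seq[i : i + 2] for i in range(len(seq) - 1)]
    for a in AMINO_ACIDS:
        for b in AMINO_ACIDS:
            out.append(pairs.count(a + b) / len(pairs))
    return np.array(out)


def test_full_feature_oracle_equivalence(random_peptides, random_table):
    """Pipeline output equals the loop-based recomputation on random inputs."""
    for pep in random_peptides:
        got = build_bio_feature(pep, random_table).vector
        want = _oracle_features(pep.sequence, random_table)
        assert np.allclose(got, want, atol=1e-10)
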