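"""Signature-matrix fusion: zone assignment, probability-map construction,
squared-difference/SSE distances, template classification, and the bundled
reference matrices (checked digit for digit against independently hard-coded
values, with pure-Python loop oracles for every distance)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lungsig import (ConfigurationError, FormatError, SignatureMatrix,
                     TemplateLibrary, ZoneBoundaries, assign_zone, assign_zones,
                     build_signature_matrix, classify, reference_signatures,
                     squared_difference, sse)

# The seven bundled reference matrices, re-typed independently of the
# packaged JSON (rows = ECG zones, columns = sound zones).
REFERENCE = {
    "1000mL_subject1": [[0.0, 0.0, 0.2421], [0.0, 0.5263, 0.0], [0.2211, 0.0, 0.0]],
    "500mL_subject1": [[0.0, 0.0, 0.0], [0.0, 0.7053, 0.0], [0.2842, 0.0, 0.0]],
    "cough_subject1": [[0.0, 0.0, 0.9053], [0.0, 0.0105, 0.0737], [0.0, 0.0, 0.0]],
    "1000mL_subject2": [[0.0, 0.0211, 0.3474], [0.0, 0.2421, 0.0], [0.1474, 0.2316, 0.0]],
    "500mL_subject2": [[0.0, 0.0, 0.0], [0.0, 0.5158, 0.0], [0.4, 0.0737, 0.0]],
    "template_subject1": [[0.0, 0.0631, 0.0807], [0.0035, 0.5438, 0.0631],
                          [0.2281, 0.007, 0.0]],
    "template_subject2": [[0.0, 0.0105, 0.4105], [0.0, 0.2211, 0.0],
                          [0.1474, 0.2, 0.0]],
}


def _loop_sse(a, b):
    """Independent hand-arithmetic oracle for the SSE distance."""
    total = 0.0
    for i in range(3):
        for j in range(3):
            total += (a[i][j] - b[i][j]) ** 2
    return total


def test_zone_assignment_boundary_convention():
    t = (1.0, 2.0)
    assert assign_zone(0.5, t) == 1
    assert assign_zone(1.0, t) == 2       # lower-inclusive at t1
    assert assign_zone(1.999, t) == 2
    assert assign_zone(2.0, t) == 3       # lower-inclusive at t2
    assert assign_zone(7.0, t) == 3
    with pytest.raises(ConfigurationError):
        assign_zone(float("nan"), t)
    with pytest.raises(ConfigurationError):
        assign_zone(1.0, (2.0, 1.0))


def test_zone_assignment_matches_loop_oracle(rng):
    t1, t2 = 0.3, 0.6
    values = rng.uniform(0, 1, 1000)
    vec = assign_zones(values, (t1, t2))
    oracle = [1 if v < t1 else (2 if v < t2 else 3) for v in values]
    assert list(vec) == oracle


def _bounds():
    return ZoneBoundaries(sound=(0.3, 0.6), ecg=(0.3, 0.6))


def test_point_mass_matrix():
    x = np.full(40, 0.45)  # sound zone 2
    y = np.full(40, 0.45)  # ecg zone 2
    m = build_signature_matrix(x, y, _bounds(), k=0)
    assert m.values[1, 1] == 1.0
    assert m.values.sum() == 1.0
    assert m.n_samples == 40


def test_counts_reproduce_reference_antidiagonal():
    # 95 frames: counts 23 / 50 / 21 in cells (1,3), (2,2), (3,1) plus one
    # frame in (1,1) — the cell the printed values leave uncounted
    x = np.concatenate([np.full(23, 0.9), np.full(50, 0.45), np.full(21, 0.1),
                        [0.1]])
    y = np.concatenate([np.full(23, 0.1), np.full(50, 0.45), np.full(21, 0.9),
                        [0.1]])
    m = build_signature_matrix(x, y, _bounds())
    expect = REFERENCE["1000mL_subject1"]
    for (i, j), printed in [((0, 2), expect[0][2]), ((1, 1), expect[1][1]),
                            ((2, 0), expect[2][0])]:
        assert m.values[i, j] == pytest.approx(printed, abs=5e-5)
    # one frame of the 95 is uncounted in the printed values; fresh builds
    # count every frame and sum to exactly 1
    assert m.values.sum() == 1.0


def test_matrix_matches_histogram_oracle(rng):
    for _ in range(100):
        n = int(rng.integers(1, 120))
        x = rng.uniform(0, 1, n)
        y = rng.uniform(0, 1, n)
        m = build_signature_matrix(x, y, _bounds())
        counts = [[0] * 3 for _ in range(3)]
        for xv, yv in zip(x, y):
            j = 0 if xv < 0.3 else (1 if xv < 0.6 else 2)
            i = 0 if yv < 0.3 else (1 if yv < 0.6 else 2)
            counts[i][j] += 1
        oracle = np.array(counts) / n
        np.testing.assert_allclose(m.values, oracle, rtol=1e-10, atol=1e-300)
        assert m.values.sum() == pytest.approx(1.0, abs=1e-12)


def test_matrix_error_contracts():
    with pytest.raises(FormatError):
        build_signature_matrix(np.zeros(3), np.zeros(4), _bounds())
    with pytest.raises(FormatError):
        build_signature_matrix(np.zeros(0), np.zeros(0), _bounds())
    with pytest.raises(FormatError):
        SignatureMatrix(np.zeros((2, 3)))
    with pytest.raises(FormatError):
        SignatureMatrix(np.full((3, 3), 0.5))  # sums to 4.5


def test_squared_difference_identity_and_symmetry():
    lib = reference_signatures()
    a = lib.entries["template_subject1"]
    b = lib.entries["1000mL_subject1"]
    assert np.all(squared_difference(a, a) == 0.0)
    np.testing.assert_array_equal(squared_difference(a, b),
                                  squared_difference(b, a))
    oracle = [[(REFERENCE["template_subject1"][i][j]
                - REFERENCE["1000mL_subject1"][i][j]) ** 2
               for j in range(3)] for i in range(3)]
    np.testing.assert_allclose(squared_difference(a, b), oracle, rtol=1e-12)


def test_sse_against_hand_arithmetic():
    lib = reference_signatures()
    t1 = lib.entries["template_subject1"]
    t2 = lib.entries["template_subject2"]
    assert sse(t1, t1) == 0.0
    # coughing sits much farther from the subject-1 template than deep breathing
    e_1000 = sse(t1, lib.entries["1000mL_subject1"])
    e_cough = sse(t1, lib.entries["cough_subject1"])
    assert e_cough > e_1000
    assert e_1000 == pytest.approx(
        _loop_sse(REFERENCE["template_subject1"], REFERENCE["1000mL_subject1"]),
        abs=1e-12)
    assert sse(t2, lib.entries["500mL_subject2"]) == pytest.approx(
        _loop_sse(REFERENCE["template_subject2"], REFERENCE["500mL_subject2"]),
        abs=1e-12)


@settings(derandomize=True, max_examples=50)
@given(st.integers(0, 2 ** 31 - 1))
def test_sse_symmetric_nonnegative(seed):
    rng = np.random.default_rng(seed)
    a = SignatureMatrix(rng.dirichlet(np.ones(9)).reshape(3, 3))
    b = SignatureMatrix(rng.dirichlet(np.ones(9)).reshape(3, 3))
    assert sse(a, b) >= 0.0
    assert sse(a, b) == pytest.approx(sse(b, a), abs=1e-300)
    assert sse(a, a) == 0.0


def test_classification_by_minimal_sse():
    lib = reference_signatures()
    target = lib.entries["500mL_subject1"]
    result = classify(target, lib)
    assert result.label == "500mL_subject1"
    assert result.sse_by_template["500mL_subject1"] == 0.0
    assert result.margin > 0

    # a 500 mL measurement against the two single-condition references:
    # the hand-computed SSE decides the expected label
    small = TemplateLibrary()
    small.add("1000mL_subject1", lib.entries["1000mL_subject1"])
    small.add("cough_subject1", lib.entries["cough_subject1"])
    expect = min(
        ["1000mL_subject1", "cough_subject1"],
        key=lambda n: _loop_sse(REFERENCE["500mL_subject1"], REFERENCE[n]))
    assert classify(target, small).label == expect


def test_point_mass_targets_classified_perfectly():
    lib = TemplateLibrary()
    cells = [(0, 0), (1, 1), (2, 2)]
    for idx, (i, j) in enumerate(cells):
        v = np.zeros((3, 3))
        v[i, j] = 1.0
        lib.add(f"c{idx}", SignatureMatrix(v))
    for idx, (i, j) in enumerate(cells):
        v = np.zeros((3, 3))
        v[i, j] = 1.0
        assert classify(SignatureMatrix(v), lib).label == f"c{idx}"


def test_empty_library_rejected():
    with pytest.raises(ConfigurationError):
        classify(SignatureMatrix(np.eye(3) / 3), TemplateLibrary())


def test_reference_fixture_digit_for_digit():
    lib = reference_signatures()
    assert set(lib.entries) == set(REFERENCE)
    for name, expect in REFERENCE.items():
        np.testing.assert_array_equal(lib.entries[name].values, np.array(expect))
        assert lib.entries[name].values.sum() <= 1.0


def test_library_json_roundtrip(tmp_path):
    lib = reference_signatures()
    lib.boundaries = ZoneBoundaries((0.1, 0.2), (0.3, 0.4))
    path = tmp_path / "lib.json"
    lib.to_json(path)
    back = TemplateLibrary.from_json(path)
    assert list(back.entries) == list(lib.entries)
    for name in lib.entries:
        np.testing.assert_array_equal(back.entries[name].values,
                                      lib.entries[name].values)
    assert back.boundaries == lib.boundaries
    with pytest.raises(ConfigurationError):
        back.add("template_subject1", lib.entries["template_subject1"])


def test_condition_level_boundaries_merge_close_levels():
    b = ZoneBoundaries.from_condition_levels(
        sound_finals={"a": [0.08], "b": [0.19], "c": [0.32], "d": [3.3]},
        ecg_finals={"a": [0.10], "b": [0.12], "c": [0.14], "d": [0.10]})
    assert b.sound == pytest.approx((0.135, 0.255))
    assert b.ecg == pytest.approx((0.11, 0.13))  # d merges into a's level
    with pytest.raises(ConfigurationError):
        ZoneBoundaries.from_condition_levels(
            sound_finals={"a": [1.0], "b": [1.0]},
            ecg_finals={"a": [1.0], "b": [2.0]})
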