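"""Unit and property tests for the MORE cryptosystem."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morenet import crypto
from morenet.crypto import (
    Ciphertext,
    CiphertextDomainError,
    EncryptionConfig,
    SingularCiphertextError,
    apply_unary,
    compare_plain,
    ct_arith,
    decrypt,
    decrypt_array,
    eigendecompose_2x2,
    encrypt,
    encrypt_array,
    generate_secret_key,
    sigmoid_direct,
)


def identity_key():
    return crypto.SecretKey(S=np.eye(2), S_inv=np.eye(2), cond=1.0, seed=0)


class TestKeyGeneration:
    def test_deterministic_per_seed(self):
        k1 = generate_secret_key(EncryptionConfig(rng_seed=17))
        k2 = generate_secret_key(EncryptionConfig(rng_seed=17))
        assert np.array_equal(k1.S, k2.S)

    def test_distinct_seeds_distinct_keys(self):
        k1 = generate_secret_key(EncryptionConfig(rng_seed=1))
        k2 = generate_secret_key(EncryptionConfig(rng_seed=2))
        assert not np.array_equal(k1.S, k2.S)

    @pytest.mark.parametrize("seed", range(12))
    def test_invariants(self, seed):
        cfg = EncryptionConfig(rng_seed=seed)
        k = generate_secret_key(cfg)
        assert abs(np.linalg.det(k.S)) > 1e-6
        assert np.max(np.abs(k.S @ k.S_inv - np.eye(2))) < 1e-12
        assert 1.0 <= k.cond <= cfg.cond_max

    def test_key_file_round_trip(self, key, tmp_path):
        crypto.save_key(key, tmp_path / "k.json")
        loaded = crypto.load_key(tmp_path / "k.json")
        # 17 significant digits round-trip float64 exactly
        assert np.array_equal(loaded.S, key.S)
        assert loaded.seed == key.seed


class TestEncryptDecrypt:
    def test_identity_key_fixed_filler(self):
        C = encrypt(3.5, identity_key(), EncryptionConfig(), r=2.0)
        assert np.allclose(C.data, [[3.5, 0.0], [0.0, 2.0]])
        assert decrypt(C, identity_key()) == 3.5

    def test_round_trip(self, key, config):
        C = encrypt(-7.25, key, config)
        assert decrypt(C, key) == pytest.approx(-7.25, abs=1e-12)

    def test_trace_det_identities(self, key, config, rng):
        for m in rng.uniform(-1e3, 1e3, size=50):
            r = float(rng.uniform(-10, 10))
            C = encrypt(m, key, config, r=r)
            assert C.trace == pytest.approx(m + r, rel=1e-9)
            assert C.det == pytest.approx(m * r, rel=1e-9, abs=1e-9)

    def test_nondeterministic_but_consistent(self, key, config):
        cts = [encrypt(1.0, key, config) for _ in range(40)]
        for a, b in zip(cts[:-1], cts[1:]):
            assert np.max(np.abs(a.data - b.data)) > config.eig_tol
            assert decrypt(a, key) == pytest.approx(1.0, abs=1e-12)

    def test_wrong_key_fails_to_decrypt(self):
        k1 = generate_secret_key(EncryptionConfig(rng_seed=5))
        k2 = generate_secret_key(EncryptionConfig(rng_seed=6))
        C = encrypt(42.0, k1, EncryptionConfig(rng_seed=7))
        assert abs(decrypt(C, k2) - 42.0) > 1e-3

    def test_nonfinite_message_rejected(self, key, config):
        with pytest.raises(ValueError):
            encrypt(math.nan, key, config)

    def test_array_round_trip_matches_scalar_path(self, key, config, rng):
        vals = rng.uniform(-50, 50, size=(7, 3))
        r = rng.uniform(-10, 10, size=(7, 3))
        arr = encrypt_array(vals, key, config, r=r)
        scal = np.array([[encrypt(m, key, config, r=rr).data for m, rr in zip(row, rrow)]
                         for row, rrow in zip(vals, r)])
        assert np.allclose(arr, scal, atol=1e-12)
        assert np.allclose(decrypt_array(arr, key), vals, atol=1e-9)

    def test_positive_only_filler_interval(self):
        cfg = EncryptionConfig(positive_only=True)
        assert cfg.r_low > 0
        with pytest.raises(ValueError):
            EncryptionConfig(positive_only=True, r_low=-1.0, r_high=2.0)


class TestArithmetic:
    def test_product_of_encryptions(self, key, config):
        assert decrypt(encrypt(6, key, config) * encrypt(7, key, config), key) == pytest.approx(42)

    def test_scalar_lift_addition(self, key, config):
        assert decrypt(encrypt(2, key, config) + 3, key) == pytest.approx(5)

    def test_division_against_plaintext(self, key, config, rng):
        a = rng.uniform(-100, 100, size=1000)
        b = rng.uniform(0.5, 100, size=1000) * rng.choice([-1, 1], size=1000)
        ca = encrypt_array(a, key, config)
        cb = encrypt_array(b, key, config)
        out = decrypt_array(crypto.cipher_div(ca, cb), key)
        assert np.allclose(out, a / b, rtol=1e-9, atol=1e-9)

    def test_division_by_singular_is_opaque(self, key, config):
        ct = encrypt(0.0, key, config)
        with pytest.raises(SingularCiphertextError) as ei:
            ct_arith("div", encrypt(1.0, key, config), ct)
        msg = str(ei.value).lower()
        assert "message" not in msg and "filler" not in msg and "eigenvalue" not in msg

    def test_requires_a_ciphertext_operand(self):
        with pytest.raises(TypeError):
            ct_arith("add", 1.0, 2.0)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        m1=st.floats(-1e3, 1e3, allow_nan=False),
        m2=st.floats(-1e3, 1e3, allow_nan=False),
        op=st.sampled_from(["add", "sub", "mul", "div"]),
    )
    def test_homomorphism_property(self, m1, m2, op):
        key = generate_secret_key(EncryptionConfig(rng_seed=4))
        config = EncryptionConfig(rng_seed=8)
        if op == "div" and abs(m2) < 1e-3:
            m2 = 1.0 + abs(m2)
        got = decrypt(ct_arith(op, encrypt(m1, key, config), encrypt(m2, key, config)), key)
        want = {"add": m1 + m2, "sub": m1 - m2, "mul": m1 * m2, "div": m1 / m2 if m2 else None}[op]
        assert got == pytest.approx(want, rel=1e-9, abs=1e-6)


class TestEigendecomposition:
    def test_triangular(self):
        l1, l2, V = eigendecompose_2x2(Ciphertext(np.array([[4.0, 1.0], [0.0, 2.0]])))
        assert sorted([l1, l2]) == [2.0, 4.0]
        C = V @ np.diag([l1, l2]) @ np.linalg.inv(V)
        assert np.allclose(C, [[4, 1], [0, 2]], atol=1e-8)

    def test_scalar_matrix_degenerate_branch(self):
        l1, l2, V = eigendecompose_2x2(Ciphertext(3.0 * np.eye(2)))
        assert l1 == l2 == 3.0
        assert np.array_equal(V, np.eye(2))

    def test_eigenvalues_are_message_and_filler(self, key, config):
        C = encrypt(1.5, key, config, r=-0.5)
        l1, l2, _ = eigendecompose_2x2(C)
        ref = sorted(np.roots([1.0, -C.trace, C.det]))
        assert sorted([l1, l2]) == pytest.approx(ref, abs=1e-9)
        assert sorted([l1, l2]) == pytest.approx([-0.5, 1.5], abs=1e-9)

    def test_complex_eigenvalues_rejected(self):
        rot = np.array([[0.0, -1.0], [1.0, 0.0]])  # eigenvalues +/- i
        with pytest.raises(crypto.CorruptedCiphertextError):
            eigendecompose_2x2(Ciphertext(rot))


class TestNonlinearFunctions:
    def test_identity_returns_same(self, key, config):
        C = encrypt(2.5, key, config)
        out = apply_unary("identity", C)
        assert np.allclose(out.data, C.data, atol=1e-10)

    def test_exp_of_zero(self, key, config):
        assert decrypt(apply_unary("exp", encrypt(0.0, key, config)), key) == pytest.approx(1.0)

    def test_sigmoid_reference_value(self, key, config):
        got = decrypt(apply_unary("sigmoid", encrypt(1.0, key, config)), key)
        assert got == pytest.approx(0.7310585786, abs=1e-8)

    @pytest.mark.parametrize("fn,ref,lo,hi", [
        ("sigmoid", lambda x: 1 / (1 + np.exp(-x)), -20, 20),
        ("tanh", np.tanh, -20, 20),
        ("exp", np.exp, -5, 5),
        ("log", np.log, 0.01, 100),
        ("sqrt", np.sqrt, 0.0, 100),
        ("reciprocal", lambda x: 1 / x, 0.1, 50),
    ])
    def test_function_matches_plaintext(self, key, fn, ref, lo, hi, rng):
        cfg = EncryptionConfig(rng_seed=3, positive_only=lo >= 0)
        vals = rng.uniform(max(lo, 1e-6) if lo >= 0 else lo, hi, size=500)
        cts = encrypt_array(vals, key, cfg)
        out = decrypt_array(crypto.apply_fn_array(fn, cts), key)
        assert np.allclose(out, ref(vals), rtol=1e-8, atol=1e-10)

    def test_domain_error_is_opaque(self, key):
        cfg = EncryptionConfig(rng_seed=3, positive_only=True)
        C = encrypt(-2.0, key, cfg)  # message negative, filler positive
        with pytest.raises(CiphertextDomainError) as ei:
            apply_unary("log", C)
        msg = str(ei.value).lower()
        assert "message" not in msg and "filler" not in msg

    def test_conjugation_closure(self, key, config):
        # arbitrary composition keeps S^-1 C S diagonal: the filler rides along
        a = encrypt(1.2, key, config)
        b = encrypt(-0.7, key, config)
        c = apply_unary("tanh", (a * b + 3.0) / encrypt(2.0, key, config))
        K = key.S_inv @ c.data @ key.S
        off = max(abs(K[0, 1]), abs(K[1, 0]))
        assert off < config.eig_tol * (1 + np.max(np.abs(c.data)))


class TestSigmoidDirect:
    def test_sigmoid_of_zero(self, key, config):
        assert decrypt(sigmoid_direct(encrypt(0.0, key, config)), key) == pytest.approx(0.5)

    def test_saturation(self, key, config):
        assert decrypt(sigmoid_direct(encrypt(30.0, key, config)), key) == pytest.approx(
            1.0, abs=1e-9)

    def test_agrees_with_eigenvalue_route(self, key, config, rng):
        vals = rng.uniform(-8, 8, size=1000)
        cts = encrypt_array(vals, key, config)
        via_eig = crypto.apply_fn_array("sigmoid", cts)
        worst = 0.0
        for i in range(1000):
            direct = sigmoid_direct(Ciphertext(cts[i]))
            worst = max(worst, float(np.max(np.abs(direct.data - via_eig[i]))))
        assert worst < 1e-8


class TestComparisons:
    def test_strict_less(self, key, config):
        assert decrypt(compare_plain(encrypt(2.0, key, config), 3.0, "lt"), key) == pytest.approx(1.0)

    def test_tie_is_strict(self):
        # exact ties are exact under the identity key (no conjugation rounding)
        k, cfg = identity_key(), EncryptionConfig()
        assert decrypt(compare_plain(encrypt(3.0, k, cfg, r=7.0), 3.0, "lt"), k) == 0.0
        assert decrypt(compare_plain(encrypt(3.0, k, cfg, r=7.0), 3.0, "le"), k) == 1.0

    def test_grid_agreement(self, key, config):
        # ~10^4 (m, s) pairs in general position (exact ties are a separate case:
        # conjugation recovers the eigenvalue only to the last ulp)
        ms = np.linspace(-5, 5, 250)
        ss = np.linspace(-4.9772, 4.9772, 10)
        for mode, op in [("lt", np.less), ("le", np.less_equal),
                         ("gt", np.greater), ("ge", np.greater_equal)]:
            for s in ss:
                cts = encrypt_array(ms, key, config)
                pred = crypto.apply_fn_array(
                    lambda lam, s=s, op=op: op(lam, s).astype(float), cts)
                got = decrypt_array(pred, key)
                assert np.allclose(got, op(ms, s).astype(float), atol=1e-9)

    def test_result_stays_encrypted(self, key, config):
        # pin the filler on the other side of s so the step separates the tracks
        out = compare_plain(encrypt(2.0, key, config, r=5.0), 3.0, "lt")
        assert isinstance(out, Ciphertext)
        # the matrix is then a non-trivial conjugation, not the plain 0/1 lift
        assert not np.allclose(out.data, np.eye(2)) and not np.allclose(out.data, 0)
        assert decrypt(out, key) == pytest.approx(1.0)
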