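"""Cable inversion: printed worked examples, degeneracies and the forward oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from motopic import (
    SystemProperties,
    VAFactors,
    forward_system_properties,
    invert_cable_parameters,
)
from motopic.cable_core import InvalidReason, invert_va_arrays

from conftest import EXEMPLARS


@pytest.mark.parametrize("label", list(EXEMPLARS))
def test_printed_tuples_reproduced(sysp, label):
    """The four published (VA -> cable) worked examples match to ~3 decimals.

    The published VA inputs are rounded to two decimals, which moves some
    cable entries by up to one unit in the third decimal; the comparison
    tolerance reflects that.
    """
    va, expected = EXEMPLARS[label]
    cable = invert_cable_parameters(sysp, VAFactors(*va))
    assert cable.valid
    got = cable.as_tuple()
    for g, e in zip(got, expected):
        assert g == pytest.approx(e, abs=2e-3)


def test_degenerate_identity_attenuation(sysp):
    """va_sd_dc * va_ds_dc = 1 has no solution (zero denominator)."""
    cable = invert_cable_parameters(sysp, VAFactors(1.0, 1.0, 0.5))
    assert not cable.valid
    assert cable.invalid_reason == InvalidReason.DEGENERATE_INPUT


def test_ac_weaker_than_dc_has_no_real_dendritic_capacitance(sysp):
    """AC attenuation cannot be weaker than DC: the C_m,D radicand goes negative."""
    va = VAFactors(0.5, 0.5, 0.9)  # va_sd_ac > va_sd_dc
    cable = invert_cable_parameters(sysp, va)
    assert not cable.valid
    assert cable.invalid_reason == InvalidReason.CMD_NOT_REAL


def test_validity_boundary_is_dc_attenuation(sysp):
    """valid <=> va_sd_ac below the DC soma-to-dendrite attenuation."""
    asd, ads = 0.8, 0.4
    for aac, ok in [(asd - 0.05, True), (asd + 0.05, False)]:
        cable = invert_cable_parameters(sysp, VAFactors(asd, ads, aac))
        assert cable.valid == ok


def test_forward_recovers_system_properties(sysp):
    """Round trip on a worked example recovers (VA, r_N, tau_m) to 1e-6."""
    va = VAFactors(0.94, 0.38, 0.69)
    cable = invert_cable_parameters(sysp, va)
    va_back, rn, tau = forward_system_properties(cable, sysp)
    assert va_back.as_tuple() == pytest.approx(va.as_tuple(), rel=1e-9)
    assert rn == pytest.approx(sysp.r_n, rel=1e-9)
    assert tau == pytest.approx(sysp.tau_m, rel=1e-9)


def test_forward_limits(sysp):
    """Uncoupled compartments attenuate fully; C_m,D -> 0 makes AC equal DC."""
    from motopic.cable_core import CableParameters

    uncoupled = CableParameters(4.0, 0.1, 1e-15, 50.0, 0.5)
    va, _, _ = forward_system_properties(uncoupled, sysp)
    assert va.as_tuple() == pytest.approx((0.0, 0.0, 0.0), abs=1e-12)

    no_cap = CableParameters(4.0, 0.1, 0.5, 50.0, 1e-15)
    va, _, _ = forward_system_properties(no_cap, sysp)
    assert va.va_sd_ac == pytest.approx(va.va_sd_dc, rel=1e-9)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    asd=st.floats(0.05, 0.99),
    ads=st.floats(0.01, 0.99),
    frac=st.floats(0.05, 0.999),
)
def test_round_trip_property(asd, ads, frac):
    """Inversion followed by the forward circuit is the identity on valid triples."""
    sysp = SystemProperties()
    aac = frac * asd  # valid region: AC attenuation stronger than DC
    cable = invert_cable_parameters(sysp, VAFactors(asd, ads, aac))
    if not cable.valid:
        return
    va_back, rn, tau = forward_system_properties(cable, sysp)
    assert va_back.as_tuple() == pytest.approx((asd, ads, aac), rel=1e-6)
    assert rn == pytest.approx(sysp.r_n, rel=1e-6)
    assert tau == pytest.approx(sysp.tau_m, rel=1e-6)


def test_vectorised_inversion_matches_scalar(sysp):
    """The array path used by sweeps agrees with the scalar dataclass path."""
    rng = np.random.default_rng(7)
    asd = rng.uniform(0, 1, 200)
    ads = rng.uniform(0, 1, 200)
    aac = rng.uniform(0, 1, 200)
    out = invert_va_arrays(sysp, asd, ads, aac)
    for i in range(200):
        cable = invert_cable_parameters(sysp, VAFactors(asd[i], ads[i], aac[i]))
        assert out["valid"][i] == cable.valid
        if cable.valid:
            got = (out["g_ms"][i], out["g_md"][i], out["g_c"][i],
                   out["c_ms"][i], out["c_md"][i])
            assert got == pytest.approx(cable.as_tuple(), rel=1e-12)


def test_system_properties_validation():
    with pytest.raises(ValueError):
        SystemProperties(p=1.5)
    with pytest.raises(ValueError):
        SystemProperties(r_n=-1.0)
    with pytest.raises(ValueError):
        VAFactors(1.2, 0.5, 0.5)
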