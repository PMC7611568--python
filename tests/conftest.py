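import pytest

from tsmr.datatypes import HarmonizedInstrument, RatioEstimate, SummaryAssociation


@pytest.fixture
def worked_ratios():
    """Three-ratio instance whose IVW/median/Q values are known by hand.

    Weights are 1/sigma^2 = 100, 400, 25 (sum 525):
    estimate = (0.2*100 + 0.15*400 + 0.1*25)/525 = 82.5/525 = 0.1571428...
    fixed se = 525**-0.5 = 0.0436435...
    Q = 100*(0.2-est)^2 + 400*(0.15-est)^2 + 25*(0.1-est)^2 = 0.2857142...
    weighted median: sorted thetas (0.1, 0.15, 0.2) with normalized weights
    (25, 400, 100)/525; midpoint positions (0.0238095, 0.4285714, 0.9047619);
    interpolating at 0.5 between the last two gives 0.1575.
    """
    return [
        RatioEstimate("rs_a", 0.2, 0.1),
        RatioEstimate("rs_b", 0.15, 0.05),
        RatioEstimate("rs_c", 0.1, 0.2),
    ]


@pytest.fixture
def make_assoc():
    """Factory for summary associations with convenient defaults."""

    def _make(
        variant_id="rs1",
        effect_allele="A",
        other_allele="G",
        beta=0.1,
        se=0.01,
        p_value=1e-10,
        eaf=0.3,
        trait_id="trait",
        **kw,
    ):
        return SummaryAssociation(
            variant_id=variant_id,
            effect_allele=effect_allele,
            other_allele=other_allele,
            beta=beta,
            se=se,
            p_value=p_value,
            eaf=eaf,
            trait_id=trait_id,
            **kw,
        )

    return _make


@pytest.fixture
def make_instrument():
    def _make(variant_id="rs1", bx=0.1, sx=0.01, by=0.05, sy=0.02):
        return HarmonizedInstrument(
            variant_id=variant_id,
            beta_exposure=bx,
            se_exposure=sx,
            beta_outcome=by,
            se_outcome=sy,
        )

    return _make
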