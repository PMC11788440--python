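import numpy as np
import pytest

from cecburden.distributions import DistributionSpec
from cecburden.risk import CECRecord, ExposureContext, TreatmentTrain, TreatmentUnit


@pytest.fixture
def ctx():
    return ExposureContext()


def point_cec(cec_id, category, cs, ef_cancer=None, ef_noncancer=None):
    return CECRecord(
        cec_id=cec_id,
        name=cec_id,
        category=category,
        cs=DistributionSpec.point(cs),
        ef_cancer=ef_cancer,
        ef_noncancer=ef_noncancer,
    )


def point_train(train_id, removals_per_unit):
    """Build a train from a list of {cec_id: removal} point maps."""
    units = tuple(
        TreatmentUnit(
            unit_id=f"u{k}",
            name=f"unit {k}",
            removal={cid: DistributionSpec.point(r) for cid, r in unit_map.items()},
        )
        for k, unit_map in enumerate(removals_per_unit)
    )
    return TreatmentTrain(train_id=train_id, units=units)


def chain_oracle(ef, df, sp, ir_daily, years, cs, removals):
    """Independently coded one-line burden formula (DALYs person^-1 y^-1)."""
    return (
        ef * df * sp * ir_daily * 365.0 * years * cs * np.prod([1.0 - r for r in removals])
        * 1e-12 / (sp * years)
    )
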