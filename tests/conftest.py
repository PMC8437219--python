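import pandas as pd
import pytest
from dataclasses import replace

from crcscreen import DEFAULT_SPEC, degenerate_sets, generate_param_set
from crcscreen.parameters import ParamSet


@pytest.fixture(scope="session")
def default_params() -> ParamSet:
    return generate_param_set(DEFAULT_SPEC)


@pytest.fixture(scope="session")
def degenerates() -> dict[str, ParamSet]:
    return degenerate_sets()


def set_prevalence(params: ParamSet, values: dict[str, float]) -> ParamSet:
    """Override starting prevalences to the same value in every band."""
    prev = params.prevalence.copy()
    for state, v in values.items():
        mask = prev["state"] == state
        prev.loc[mask, ["value", "ci_lower", "ci_upper"]] = v
    return replace(params, prevalence=prev)


def set_transitions(params: ParamSet, values: dict[tuple[str, str], float]) -> ParamSet:
    """Override transition rates to age- and sex-independent constants."""
    trans = params.transitions.copy()
    for (fs, ts), v in values.items():
        mask = (trans["from_state"] == fs) & (trans["to_state"] == ts)
        trans.loc[mask, ["value", "ci_lower", "ci_upper"]] = v
    return replace(params, transitions=trans)


def set_test_performance(
    params: ParamSet,
    modality: str,
    sensitivity: dict[str, float] | None = None,
    specificity: float | None = None,
) -> ParamSet:
    tp = params.test_performance.copy()
    if sensitivity:
        for state, v in sensitivity.items():
            mask = (
                (tp["modality"] == modality)
                & (tp["measure"] == "sensitivity")
                & (tp["state"] == state)
            )
            tp.loc[mask, "value"] = v
    if specificity is not None:
        mask = (tp["modality"] == modality) & (tp["measure"] == "specificity")
        tp.loc[mask, "value"] = specificity
    return replace(params, test_performance=tp)


def set_constant_mortality(
    params: ParamSet, q: float, crc: float | None = None, ysd_cap: int | None = None
) -> ParamSet:
    """Constant all-cause rate (with a consistent decreasing life table) and,
    optionally, constant CRC-specific mortality under a custom cap."""
    mort = params.all_cause_mortality.copy()
    mort["value"] = q
    le = params.life_expectancy.copy()
    le["value"] = 120.0 - le["age"].astype(float)
    out = replace(params, all_cause_mortality=mort, life_expectancy=le)
    if crc is not None:
        cap = params.ysd_cap if ysd_cap is None else ysd_cap
        rows = [
            {"mode": mode, "years_since_dx": ysd, "value": crc}
            for mode in ("screen", "symptom")
            for ysd in range(cap + 1)
        ]
        out = replace(out, crc_mortality=pd.DataFrame(rows), ysd_cap=cap)
    return out
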