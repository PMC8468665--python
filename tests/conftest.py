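import numpy as np
import pytest

import cnvscreen as cs


@pytest.fixture(scope="session")
def default_cfg() -> cs.SimulationConfig:
    return cs.SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def layout(default_cfg) -> cs.GenomeLayout:
    return cs.make_genome(default_cfg)


@pytest.fixture(scope="session")
def small_study():
    """A reduced cohort that still exercises every pipeline stage quickly."""
    cfg = cs.SimulationConfig(
        seed=13,
        n_cases=8,
        n_controls=24,
        event_spec=[
            cs.EventSpec(3, (120_000, 130_000), n_case_carriers=1, label="ultra_rare"),
            cs.EventSpec(3, (90_000, 100_000), n_case_carriers=1, label="ultra_rare"),
            cs.EventSpec(3, (60_000, 70_000), 2, 6, "common_polymorphism"),
            cs.EventSpec(1, (30_000, 36_000), 2, 6, "common_polymorphism"),
        ],
    )
    layout = cs.make_genome(cfg)
    truth = cs.plant_truth(layout, cfg)
    samples = cs.simulate_intensities(layout, truth, cfg)
    return cfg, layout, truth, samples


def make_random_calls(
    rng: np.random.Generator,
    n: int,
    caller_ids=("penn-like",),
    samples=("s1", "s2", "s3"),
    grid: int = 100,
    max_pos: int = 50_000,
    confidence_range=(0.0, 80.0),
) -> list[cs.CnvCall]:
    """Random non-duplicate calls on a coarse grid (so exact matches and
    containments occur often)."""
    calls: list[cs.CnvCall] = []
    seen: set[tuple] = set()
    while len(calls) < n:
        start = int(rng.integers(1, max_pos // grid)) * grid + 1
        end = start + int(rng.integers(1, 30)) * grid - 1
        cn = int(rng.choice([0, 1, 3, 4]))
        typ = "DEL" if cn < 2 else "DUP"
        sample = str(rng.choice(list(samples)))
        caller = str(rng.choice(list(caller_ids)))
        key = (sample, caller, "1", start, end, typ)
        if key in seen:
            continue
        seen.add(key)
        calls.append(
            cs.CnvCall(
                sample_id=sample,
                caller_id=caller,
                chrom="1",
                start=start,
                end=end,
                type=typ,
                copy_number=cn,
                n_probes=int(rng.integers(1, 60)),
                confidence=round(float(rng.uniform(*confidence_range)), 4),
            )
        )
    return calls


@pytest.fixture(scope="session")
def random_calls_factory():
    return make_random_calls
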