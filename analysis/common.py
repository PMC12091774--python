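"""Shared plumbing for the numbered analysis scripts.

The study cohort is synthetic and fully determined by a root seed: a
Sweden-like 15-year climate over three regions and 50,000 MI
hospitalizations whose intensity follows the directional temperature-
variability crossbasis with known truth (upward lag-0 log-OR 0.009,
downward lag-2 log-OR 0.003, both inside the lag-spline span).  Script 01
materialises the cohort as CSVs under scratch/; later scripts read those
files through the validated CSV contracts, regenerating them if absent.
"""

from pathlib import Path

import pandas as pd

import tvmi
from tvmi import io
from tvmi.synth import smooth_lag_curve

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"

DEFAULT_SEED = 20250926
TRUTH_UP_LAG0 = 0.009
TRUTH_DN_LAG2 = 0.003
N_EVENTS = 50_000


def study_truth() -> tvmi.TrueEffect:
    return tvmi.TrueEffect(
        upward_logor_by_lag=smooth_lag_curve(0, TRUTH_UP_LAG0),
        downward_logor_by_lag=smooth_lag_curve(2, TRUTH_DN_LAG2),
    )


def build_cohort(seed: int = DEFAULT_SEED) -> tvmi.SyntheticCohort:
    return tvmi.generate_cohort(truth=study_truth(), n_events=N_EVENTS, seed=seed)


def materialise_cohort(seed: int = DEFAULT_SEED, outdir: Path = SCRATCH) -> Path:
    outdir = Path(outdir)
    if not (outdir / "events.csv").exists():
        build_cohort(seed).to_csvs(outdir)
    return outdir


def load_cohort_frames(seed: int = DEFAULT_SEED):
    """(temperature, events, pollutants, holidays) via the CSV contracts."""
    d = materialise_cohort(seed)
    return (
        io.read_temperature_csv(d / "temperature.csv"),
        io.read_events_csv(d / "events.csv"),
        io.read_pollutants_csv(d / "pollutants.csv"),
        io.read_holidays_csv(d / "holidays.csv"),
    )


def save_table(frame: pd.DataFrame, name: str) -> Path:
    RESULTS.mkdir(parents=True, exist_ok=True)
    path = RESULTS / name
    frame.to_csv(path, index=False, float_format="%.6g")
    return path
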