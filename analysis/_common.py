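"""Shared study configuration and artifact locations for the numbered
analysis scripts.  Run the scripts in order from the repository root:

    python analysis/01_simulate_cohort.py
    python analysis/02_balanced_split.py
    ...

Each stage reads its predecessors' outputs from results/analysis/.
"""

from pathlib import Path
import sys

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

RESULTS = ROOT / "results" / "analysis"

from postop_recovery.config import validate_config  # noqa: E402

SEED = 20230502


def study_config():
    """125-patient synthetic cohort at the default clinical conditions;
    storage cadences coarsened for cohort-scale runtime (see
    docs/methods.md, 'Problem sizes')."""
    return validate_config({
        "seed": SEED,
        "generator": {"n_patients": 125, "chest_hr_dt": 32.0,
                      "chest_rr_dt": 32.0, "wrist_dt": 30.0},
        "features": {"welch_fs": 2.0},
    })
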