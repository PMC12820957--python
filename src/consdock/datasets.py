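"""Small published reference datasets shipped with the package.

These are transcriptions of published docking results for the E/Z
geometric isomers of the acaricide fenpyroximate at mitochondrial
complex I — an activity-cliff pair that structure-only models cannot
separate — together with the published KDE-derived IFDScore decision
threshold and the published confusion-matrix counts for the scoring-based
inhibitor classification tasks.  They serve as worked examples and
regression anchors for the consensus machinery.
"""

from __future__ import annotations

import io as _io

import pandas as pd

from .classify import ThresholdModel
from .io import Direction, ScoreTable, ScoringFunctionSpec

__all__ = [
    "fenpyroximate_ci_specs",
    "fenpyroximate_ci_scores",
    "ifdscore_ci_threshold",
    "ci_confusion_counts",
    "ciii_goldscore_confusion_counts",
]

# Eleven scoring functions of the GOLD + Glide cross-docking campaign.
# The three GOLD fitness functions are higher-is-better; docking scores,
# IFDScore and all binding-energy estimates are lower-is-better.
_SPECS = [
    ("GOLD ChemPLP Fitness", "GOLD", Direction.higher_is_better),
    ("GOLD ChemScore Fitness", "GOLD", Direction.higher_is_better),
    ("GOLD GoldScore Fitness", "GOLD", Direction.higher_is_better),
    ("MMGBSA dG Bind (GOLD)", "GOLD", Direction.lower_is_better),
    ("MBAE ASET Total Energy-S-OPLS (GOLD)", "GOLD", Direction.lower_is_better),
    ("MBAE Del Total Energy-S-OPLS (GOLD)", "GOLD", Direction.lower_is_better),
    ("Glide docking score", "Glide", Direction.lower_is_better),
    ("Glide IFDScore", "Glide", Direction.lower_is_better),
    ("MMGBSA dG Bind (Glide)", "Glide", Direction.lower_is_better),
    ("MBAE ASET Total Energy-S-OPLS (Glide)", "Glide", Direction.lower_is_better),
    ("MBAE Del Total Energy-S-OPLS (Glide)", "Glide", Direction.lower_is_better),
]

# Published docking scores of E- and Z-fenpyroximate at complex I,
# one row per scoring function: (name, E-FPM, Z-FPM).
_FPM_SCORES = [
    ("GOLD ChemPLP Fitness", 86.32, 80.59),
    ("GOLD ChemScore Fitness", 28.77, 27.47),
    ("GOLD GoldScore Fitness", 62.01, 51.33),
    ("MMGBSA dG Bind (GOLD)", -53.22, -40.61),
    ("MBAE ASET Total Energy-S-OPLS (GOLD)", -251.30, -244.66),
    ("MBAE Del Total Energy-S-OPLS (GOLD)", -162.35, -168.63),
    ("Glide docking score", -9.14, -8.70),
    ("Glide IFDScore", -3173.87, -3170.89),
    ("MMGBSA dG Bind (Glide)", -56.31, -34.79),
    ("MBAE ASET Total Energy-S-OPLS (Glide)", -241.70, -235.88),
    ("MBAE Del Total Energy-S-OPLS (Glide)", -203.43, -206.22),
]


def fenpyroximate_ci_specs() -> list[ScoringFunctionSpec]:
    return [ScoringFunctionSpec(n, p, d) for n, p, d in _SPECS]


def fenpyroximate_ci_scores() -> ScoreTable:
    """The E-/Z-fenpyroximate score pair at complex I: 2 ligands x 11
    scoring functions, no missing values."""
    df = pd.DataFrame(
        {name: {"E-FPM": e, "Z-FPM": z} for name, e, z in _FPM_SCORES},
        index=pd.Index(["E-FPM", "Z-FPM"], name="ligand_id"),
    )
    return ScoreTable(target_id="CI", scores=df)


def ifdscore_ci_threshold() -> ThresholdModel:
    """The published KDE-intersection IFDScore cutoff at complex I:
    ligands scoring lower than -3170.75 are called CI inhibitors."""
    return ThresholdModel(
        function_name="Glide IFDScore",
        threshold=-3170.75,
        positive_side="below",
        domain="score",
    )


def ci_confusion_counts() -> dict[str, int]:
    """Published confusion counts of the IFDScore-based complex-I
    classification (14 CI inhibitors vs 14 non-CI-inhibitors)."""
    return {"tp": 12, "fn": 2, "fp": 4, "tn": 10}


def ciii_goldscore_confusion_counts() -> dict[str, int]:
    """Published confusion counts of the GoldScore-based complex-III
    classification (11 CIII inhibitors vs 17 others; one ligand failed
    to dock and is counted with the negatives)."""
    return {"tp": 10, "fn": 1, "fp": 2, "tn": 15}
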