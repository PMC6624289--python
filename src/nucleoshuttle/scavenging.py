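"""H2O2 scavenging activity from ferrous-phenanthroline absorbance readings.

In this assay H2O2 oxidizes Fe(II), preventing formation of the orange
tri-phenanthroline complex read at 510 nm.  A scavenger protects the Fe(II)
signal, so after subtracting the background blank, activity is the sample
absorbance divided by the negative-control absorbance (reaction mix without
test compound and without H2O2):

    activity = (A_sample - A_background) / (A_negative_control - A_background)

Values near 1 mean full protection (strong scavenging); values near 0 mean
none.  Concentration series are carried as metadata only; no dose-response
curve is fitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Tuple, Union

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AbsorbanceSet",
    "ScavengingResult",
    "scavenging_activity",
    "read_absorbance_csv",
    "write_activity_csv",
]


@dataclass(frozen=True)
class AbsorbanceSet:
    """Plate-reader absorbances at 510 nm for one assay run."""

    a_background: float
    a_negative_control: float
    samples: Tuple[Tuple[str, str, float], ...]  # (compound, concentration, A)

    def validate(self) -> None:
        if self.a_background < 0 or self.a_negative_control < 0:
            raise ValueError("absorbances must be non-negative")
        if any(a < 0 for _, _, a in self.samples):
            raise ValueError("sample absorbances must be non-negative")
        if self.a_negative_control - self.a_background <= 0:
            raise ValueError(
                "negative-control absorbance must exceed the background "
                f"(got {self.a_negative_control} vs {self.a_background})"
            )


@dataclass(frozen=True)
class ScavengingResult:
    compound: str
    concentration: str
    activity: float
    clipped: bool = False


def scavenging_activity(s: AbsorbanceSet) -> List[ScavengingResult]:
    """Background-corrected activity per sample; negatives clip to 0."""
    s.validate()
    denom = s.a_negative_control - s.a_background
    out: List[ScavengingResult] = []
    for compound, conc, a in s.samples:
        num = a - s.a_background
        clipped = num < 0
        if clipped:
            logger.warning(
                "sample %s @ %s reads below background (%.4g < %.4g); "
                "activity clipped to 0",
                compound, conc, a, s.a_background,
            )
            num = 0.0
        out.append(
            ScavengingResult(
                compound=compound,
                concentration=conc,
                activity=num / denom,
                clipped=clipped,
            )
        )
    return out


def read_absorbance_csv(path: Union[str, Path]) -> AbsorbanceSet:
    """Load a plate CSV with columns compound, concentration, absorbance, role.

    ``role`` distinguishes ``sample`` (default when blank), the single
    ``negative_control`` row and the single ``background`` row.
    """
    frame = pd.read_csv(path, dtype={"compound": str, "concentration": str})
    if "role" not in frame.columns:
        frame["role"] = "sample"
    frame["role"] = frame["role"].fillna("sample")
    bg = frame[frame["role"] == "background"]
    nc = frame[frame["role"] == "negative_control"]
    if len(bg) != 1 or len(nc) != 1:
        raise ValueError(
            "plate CSV must contain exactly one background and one "
            f"negative_control row (found {len(bg)} and {len(nc)})"
        )
    samples = tuple(
        (str(r["compound"]), str(r["concentration"]), float(r["absorbance"]))
        for _, r in frame[frame["role"] == "sample"].iterrows()
    )
    return AbsorbanceSet(
        a_background=float(bg["absorbance"].iloc[0]),
        a_negative_control=float(nc["absorbance"].iloc[0]),
        samples=samples,
    )


def write_activity_csv(results: List[ScavengingResult], path: Union[str, Path]) -> None:
    pd.DataFrame(
        [
            {
                "compound": r.compound,
                "concentration": r.concentration,
                "activity": r.activity,
                "clipped": r.clipped,
            }
            for r in results
        ],
        columns=["compound", "concentration", "activity", "clipped"],
    ).to_csv(Path(path), index=False)
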