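"""Long-term urinary toxicity endpoint from IPSS trajectories.

The International Prostate Symptom Score (IPSS, 0–35) typically rises
transiently after seed implantation and then drifts back toward baseline.
"Resolution" means a post-implant score returning to within 2 points of the
patient's baseline; a patient who fails to resolve within 12 months is
labeled as having long-term urinary toxicity (label 1).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["IPSSRecord", "label_toxicity"]


@dataclass
class IPSSRecord:
    """Baseline IPSS plus the follow-up series for one patient."""

    patient_id: str
    baseline_ipss: int
    followups: list[tuple[float, int]]  # (months since implant, IPSS)

    def __post_init__(self) -> None:
        scores = [self.baseline_ipss] + [s for _, s in self.followups]
        if any(not 0 <= s <= 35 for s in scores):
            raise ValueError(f"{self.patient_id}: IPSS scores must lie in [0, 35]")
        times = [t for t, _ in self.followups]
        if any(t <= 0 for t in times) or any(
            b <= a for a, b in zip(times, times[1:])
        ):
            raise ValueError(
                f"{self.patient_id}: follow-up times must be positive and increasing"
            )


def label_toxicity(
    record: IPSSRecord,
    horizon_months: float = 12.0,
    tolerance_points: int = 2,
) -> int:
    """1 if no follow-up within the horizon returned to within ``tolerance``
    points of baseline, else 0.

    Resolution is one-sided — a score at or below ``baseline + tolerance``
    qualifies, so improvement below baseline counts as resolved. A single
    qualifying visit suffices; sustained resolution is not required.
    """
    within = [s for t, s in record.followups if t <= horizon_months]
    if not within:
        raise ValueError(
            f"{record.patient_id}: no follow-up within {horizon_months} months"
        )
    resolved = any(s <= record.baseline_ipss + tolerance_points for s in within)
    return 0 if resolved else 1
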