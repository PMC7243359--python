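"""Patient-level record types shared by the advisor, MAP estimator, and cohort tools."""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Iterator, Optional

from .models import CovariateSet
from .simulate import DoseEvent

__all__ = ["Observation", "ObservationSet", "PatientRecord"]


@dataclass(frozen=True)
class Observation:
    """A measured plasma concentration."""

    time: datetime
    concentration_mg_L: float
    drug: str = ""
    kind: Optional[str] = None  # 'trough' | 'peak' | None

    def __post_init__(self) -> None:
        if self.concentration_mg_L < 0:
            raise ValueError("concentration_mg_L must be >= 0")
        if self.time.tzinfo is None:
            object.__setattr__(self, "time", self.time.replace(tzinfo=timezone.utc))


@dataclass(frozen=True)
class ObservationSet:
    """Measured plasma concentrations for one patient, time-ordered."""

    observations: tuple[Observation, ...] = ()

    def __post_init__(self) -> None:
        obs = tuple(sorted(self.observations, key=lambda o: o.time))
        object.__setattr__(self, "observations", obs)

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self) -> Iterator[Observation]:
        return iter(self.observations)

    def for_drug(self, drug: str) -> "ObservationSet":
        key = drug.strip().lower()
        return ObservationSet(
            tuple(o for o in self.observations if o.drug.strip().lower() in ("", key))
        )


@dataclass
class PatientRecord:
    """Time-stamped covariates, dose-event history, and measured levels."""

    id: str
    covariates: list[CovariateSet] = field(default_factory=list)
    doses: list[DoseEvent] = field(default_factory=list)
    observations: ObservationSet = field(default_factory=ObservationSet)

    def __post_init__(self) -> None:
        if not self.covariates:
            raise ValueError("a patient record needs at least one covariate set")
        times = [c.time for c in self.covariates]
        if any(t is None for t in times):
            raise ValueError("covariate sets in a patient record must be time-stamped")
        self.covariates = sorted(self.covariates, key=lambda c: c.time)
        self.doses = sorted(self.doses, key=lambda d: d.start_time)

    def covariates_at(self, when: Optional[datetime] = None) -> CovariateSet:
        """Most recent covariate set at or before ``when`` (default: latest)."""
        if when is None:
            return self.covariates[-1]
        eligible = [c for c in self.covariates if c.time <= when]
        if not eligible:
            raise ValueError(
                f"patient {self.id}: no covariates at or before {when.isoformat()}"
            )
        return eligible[-1]

    def doses_for(self, drug: str) -> list[DoseEvent]:
        key = drug.strip().lower()
        return [d for d in self.doses if d.drug.strip().lower() == key]
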