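"""Demographic parameterisation for two-lineage divergence models.

Five classical speciation scenarios are supported, differing only in
when (backward in time) gene flow between the two descendant lineages
is active:

* ``SI``  — strict isolation: no gene flow after the split.
* ``IM``  — isolation with migration: gene flow for the whole post-split
  period.
* ``AM``  — ancient migration: gene flow only early after the split,
  ceasing ``t_contact`` generations before the present.
* ``SC``  — secondary contact: gene flow only during the most recent
  ``t_contact`` generations.
* ``SCS`` — secondary contact with a stop: gene flow during
  ``[t_stop, t_contact)`` generations before the present.

All times are in generations before the present, all sizes are diploid
effective sizes, and migration parameters are per-generation migrant
proportions.  ``m_mj`` is the forward-in-time proportion of migrants
from deme A (the larger, "maximus-like" lineage) into deme B; backward
in time it is therefore the probability that a lineage currently in
deme B traces its ancestry into deme A.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Optional

__all__ = [
    "DemographicParams",
    "ModelSpec",
    "ParameterError",
    "ModelSpecError",
    "MODELS",
]

PARAM_FIELDS = (
    "n_anc",
    "n_pma",
    "n_pja",
    "t_split",
    "t_contact",
    "t_stop",
    "m_mj",
    "m_jm",
)

#: Epoch parameters, in the order outer-to-inner.
_TIME_FIELDS = ("t_split", "t_contact", "t_stop")
_MIGRATION_FIELDS = ("m_mj", "m_jm")


class ParameterError(ValueError):
    """Raised for non-finite, negative or out-of-order demographic parameters."""


class ModelSpecError(ValueError):
    """Raised when a model specification is internally inconsistent."""


@dataclass(frozen=True)
class DemographicParams:
    """The eight parameters of the two-deme divergence models.

    Parameters
    ----------
    n_anc, n_pma, n_pja
        Diploid effective sizes of the ancestral population and of the
        two descendant lineages (deme A ~ *P. maximus*-like, deme B ~
        *P. jacobaeus*-like).
    t_split
        Split time in generations before present (T_S).
    t_contact
        Epoch boundary T_1 (meaning depends on the model; 0 if unused).
    t_stop
        Epoch boundary T_2, the recent end of gene flow under SCS
        (0 if unused).
    m_mj, m_jm
        Per-generation migrant proportions A->B and B->A (forward in
        time).
    """

    n_anc: float
    n_pma: float
    n_pja: float
    t_split: float
    t_contact: float = 0.0
    t_stop: float = 0.0
    m_mj: float = 0.0
    m_jm: float = 0.0

    def validate(self) -> "DemographicParams":
        import math

        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ParameterError(f"{f.name} is not finite: {v!r}")
        if min(self.n_anc, self.n_pma, self.n_pja) <= 0:
            raise ParameterError("effective sizes must be > 0")
        if not (0 <= self.t_stop <= self.t_contact <= self.t_split):
            raise ParameterError(
                "epoch times must satisfy 0 <= t_stop <= t_contact <= t_split; "
                f"got t_stop={self.t_stop}, t_contact={self.t_contact}, "
                f"t_split={self.t_split}"
            )
        if not (0 <= self.m_mj < 1 and 0 <= self.m_jm < 1):
            raise ParameterError("migration proportions must lie in [0, 1)")
        return self

    def replace(self, **kw) -> "DemographicParams":
        return replace(self, **kw)

    def as_dict(self) -> dict:
        return {f: getattr(self, f) for f in PARAM_FIELDS}


@dataclass(frozen=True)
class ModelSpec:
    """A divergence model: its name and which parameters are free.

    The free-parameter sets are nested: SI frees the three sizes and the
    split time (k=4); IM adds the two migration rates (k=6); AM and SC
    add ``t_contact`` (k=7); SCS adds ``t_stop`` (k=8).
    """

    name: str
    free_params: tuple

    def __post_init__(self):
        unknown = set(self.free_params) - set(PARAM_FIELDS)
        if unknown:
            raise ModelSpecError(f"unknown parameters: {sorted(unknown)}")
        free = set(self.free_params)
        if "t_stop" in free and "t_contact" not in free:
            raise ModelSpecError("a model with t_stop must also define t_contact")
        if any(f in free for f in _MIGRATION_FIELDS) and not all(
            f in free for f in _MIGRATION_FIELDS
        ):
            raise ModelSpecError("migration must free both m_mj and m_jm")
        if ("t_contact" in free or "t_stop" in free) and "m_mj" not in free:
            raise ModelSpecError(
                "epoch boundaries t_contact/t_stop are meaningless without migration"
            )

    @property
    def k(self) -> int:
        """Number of free parameters (used by AIC)."""
        return len(self.free_params)

    @property
    def has_migration(self) -> bool:
        return "m_mj" in self.free_params

    def migration_window(self, params: DemographicParams) -> Optional[tuple]:
        """Backward-time interval ``[lo, hi)`` during which lineage
        migration is active, or ``None`` for strict isolation.

        SI: never; IM: [0, t_split); AM: [t_contact, t_split);
        SC: [0, t_contact); SCS: [t_stop, t_contact).
        """
        if self.name == "SI" or not self.has_migration:
            return None
        if self.name == "IM":
            return (0.0, params.t_split)
        if self.name == "AM":
            return (params.t_contact, params.t_split)
        if self.name == "SC":
            return (0.0, params.t_contact)
        if self.name == "SCS":
            return (params.t_stop, params.t_contact)
        raise ModelSpecError(f"unknown model name {self.name!r}")

    def constrain(self, params: DemographicParams) -> DemographicParams:
        """Zero out parameters the model does not define."""
        kw = {}
        if not self.has_migration:
            kw.update(m_mj=0.0, m_jm=0.0)
        if "t_contact" not in self.free_params:
            kw.update(t_contact=0.0)
        if "t_stop" not in self.free_params:
            kw.update(t_stop=0.0)
        return params.replace(**kw) if kw else params


_BASE = ("n_anc", "n_pma", "n_pja", "t_split")

MODELS = {
    "SI": ModelSpec("SI", _BASE),
    "IM": ModelSpec("IM", _BASE + ("m_mj", "m_jm")),
    "AM": ModelSpec("AM", _BASE + ("m_mj", "m_jm", "t_contact")),
    "SC": ModelSpec("SC", _BASE + ("m_mj", "m_jm", "t_contact")),
    "SCS": ModelSpec("SCS", _BASE + ("m_mj", "m_jm", "t_contact", "t_stop")),
}
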