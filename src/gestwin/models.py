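"""Model specifications: named combinations of locus classes and constraints.

A :class:`ModelSpec` bundles the locus classes of a simulation model, marks
which class parameters are free (to be optimised) versus fixed, and records
whether the sum-statistic meta-modeling stage applies.  The five canonical
models are:

* ``M0`` — no genetic factors (baseline only).
* ``M1`` — one constant-effect class; ``gamma``, ``maf``, ``count`` free.
* ``M2`` — two constant-effect classes; the second has ``count`` pinned to 1.
* ``M3`` — one free constant-effect class plus four fixed varying-effect
  classes with windows peaking at gestational days 230/237/244/258
  (``sigma`` 10 d), effect masses 100/80/60/-100 and MAFs
  0.005/0.01/0.015/0.3.
* ``M4`` — five constant-effect classes: the first pinned to a given best
  constant class, the rest inheriting ``maf``/``count`` from the varying
  classes of M3 with only their ``gamma`` free; no meta-modeling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import yaml

from .genotypes import CONSTANT, VARYING, LocusClass
from .hazard import BaselineHazard, default_baseline

__all__ = [
    "ModelSpec",
    "FREE_PARAM_NAMES",
    "model_m0",
    "model_m1",
    "model_m2",
    "model_m3",
    "model_m4",
    "m3_varying_classes",
    "builtin_model",
    "read_model_spec",
    "write_model_spec",
]

FREE_PARAM_NAMES = ("gamma", "maf", "count")


@dataclass(frozen=True)
class ModelSpec:
    """A named model: locus classes, free/fixed parameter masks, constraints."""

    name: str
    classes: tuple[LocusClass, ...] = ()
    free: tuple[frozenset, ...] = ()
    use_metamodel: bool = False
    engine: str = "auto"
    baseline: BaselineHazard | None = None

    def __post_init__(self) -> None:
        if len(self.free) != len(self.classes):
            raise ValueError("free mask list must match number of classes")
        for lc, mask in zip(self.classes, self.free):
            bad = set(mask) - set(FREE_PARAM_NAMES)
            if bad:
                raise ValueError(f"unknown free parameters {sorted(bad)}")
            if lc.kind == VARYING and mask:
                raise ValueError("varying-effect classes carry fixed parameters only")
        if self.engine not in ("auto", "analytic", "iterative"):
            raise ValueError(f"unknown engine policy {self.engine!r}")

    @property
    def n_loci(self) -> int:
        return sum(lc.count for lc in self.classes)

    @property
    def has_varying(self) -> bool:
        return any(lc.kind == VARYING for lc in self.classes)

    @property
    def n_free_params(self) -> int:
        return sum(len(mask) for mask in self.free)

    @property
    def free_class_indices(self) -> tuple[int, ...]:
        return tuple(k for k, mask in enumerate(self.free) if mask)

    def resolved_baseline(self) -> BaselineHazard:
        return self.baseline if self.baseline is not None else default_baseline()

    def with_classes(self, classes: Sequence[LocusClass]) -> "ModelSpec":
        """A copy with concrete classes substituted (free masks retained)."""
        classes = tuple(classes)
        if len(classes) != len(self.classes):
            raise ValueError("class count mismatch")
        return replace(self, classes=classes)

    def to_dict(self) -> dict:
        out: dict = {
            "name": self.name,
            "metamodel": self.use_metamodel,
            "engine": self.engine,
            "classes": [],
        }
        for lc, mask in zip(self.classes, self.free):
            d = {"kind": lc.kind, "gamma": lc.gamma, "maf": lc.maf, "count": lc.count}
            if lc.kind == VARYING:
                d["mu"] = lc.mu
                d["sigma"] = lc.sigma
            if mask:
                d["free"] = sorted(mask)
            out["classes"].append(d)
        if self.baseline is not None:
            out["baseline"] = {
                "rate": self.baseline.rate,
                "shape": self.baseline.shape,
                "origin_day": self.baseline.origin_day,
                "cap_day": self.baseline.cap_day,
            }
        return out


def m3_varying_classes() -> tuple[LocusClass, ...]:
    """The four fixed Gaussian-window classes of model M3."""
    mus = (230.0, 237.0, 244.0, 258.0)
    gammas = (100.0, 80.0, 60.0, -100.0)
    mafs = (0.005, 0.01, 0.015, 0.3)
    return tuple(
        LocusClass(VARYING, gamma=g, maf=p, count=1, mu=m, sigma=10.0)
        for g, p, m in zip(gammas, mafs, mus)
    )


def _placeholder_constant(gamma: float = 1.0, maf: float = 0.1, count: int = 1) -> LocusClass:
    return LocusClass(CONSTANT, gamma=gamma, maf=maf, count=count)


def model_m0() -> ModelSpec:
    return ModelSpec(name="M0")


def model_m1(template: LocusClass | None = None) -> ModelSpec:
    lc = template if template is not None else _placeholder_constant()
    return ModelSpec(
        name="M1",
        classes=(lc,),
        free=(frozenset(FREE_PARAM_NAMES),),
        use_metamodel=True,
    )


def model_m2(
    template1: LocusClass | None = None, template2: LocusClass | None = None
) -> ModelSpec:
    lc1 = template1 if template1 is not None else _placeholder_constant()
    lc2 = template2 if template2 is not None else _placeholder_constant(count=1)
    if lc2.count != 1:
        raise ValueError("the second class of M2 has count pinned to 1")
    return ModelSpec(
        name="M2",
        classes=(lc1, lc2),
        free=(frozenset(FREE_PARAM_NAMES), frozenset({"gamma", "maf"})),
        use_metamodel=True,
    )


def model_m3(template: LocusClass | None = None) -> ModelSpec:
    lc = template if template is not None else _placeholder_constant()
    return ModelSpec(
        name="M3",
        classes=(lc,) + m3_varying_classes(),
        free=(frozenset(FREE_PARAM_NAMES),) + (frozenset(),) * 4,
        use_metamodel=True,
        engine="iterative",
    )


def model_m4(best_constant: LocusClass) -> ModelSpec:
    """Five constant classes: class 1 fixed at a given best fit, rest gamma-free."""
    if best_constant.kind != CONSTANT:
        raise ValueError("M4 requires a constant-effect class for class 1")
    rest = tuple(
        LocusClass(CONSTANT, gamma=0.0, maf=v.maf, count=v.count)
        for v in m3_varying_classes()
    )
    return ModelSpec(
        name="M4",
        classes=(best_constant,) + rest,
        free=(frozenset(),) + (frozenset({"gamma"}),) * 4,
        use_metamodel=False,
    )


def builtin_model(name: str, **kwargs) -> ModelSpec:
    """Look up a canonical model by name (case-insensitive)."""
    builders = {"m0": model_m0, "m1": model_m1, "m2": model_m2, "m3": model_m3, "m4": model_m4}
    key = name.lower()
    if key not in builders:
        raise KeyError(f"unknown builtin model {name!r}; choose from M0..M4")
    return builders[key](**kwargs)


def read_model_spec(path) -> ModelSpec:
    """Read a model specification from a YAML file (see :meth:`ModelSpec.to_dict`)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "classes" not in raw:
        raise ValueError(f"{path}: not a model spec (missing 'classes')")
    classes, free = [], []
    for d in raw["classes"]:
        kind = d["kind"]
        classes.append(
            LocusClass(
                kind,
                gamma=float(d["gamma"]),
                maf=float(d["maf"]),
                count=int(d.get("count", 1)),
                mu=float(d["mu"]) if kind == VARYING else None,
                sigma=float(d["sigma"]) if kind == VARYING else None,
            )
        )
        free.append(frozenset(d.get("free", ())))
    baseline = None
    if "baseline" in raw:
        b = raw["baseline"]
        baseline = BaselineHazard(
            rate=float(b["rate"]),
            shape=float(b["shape"]),
            origin_day=int(b.get("origin_day", 150)),
            cap_day=int(b.get("cap_day", 300)),
        )
    return ModelSpec(
        name=str(raw.get("name", "custom")),
        classes=tuple(classes),
        free=tuple(free),
        use_metamodel=bool(raw.get("metamodel", False)),
        engine=str(raw.get("engine", "auto")),
        baseline=baseline,
    )


def write_model_spec(spec: ModelSpec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=False)
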