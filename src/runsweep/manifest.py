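"""Parameter-description schema for sweepable model apps.

A model app declares its control parameters once, in a small JSON manifest.
From that single declaration the package derives both the single-run default
configuration and the sampling specification used for random parameter
sweeps: each parameter either stays constant at a chosen value or is sampled
uniformly from a user-restricted sub-range / sub-set of its legal values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

__all__ = [
    "ParameterSpec",
    "AppManifest",
    "SamplingDirective",
    "SamplingSpec",
    "ManifestError",
    "parse_manifest",
    "default_sampling_spec",
    "validate_sampling_spec",
    "load_sampling_spec",
]

#: legal parameter kinds. string/filename/output parameters are passed
#: through as constants and never sampled.
KINDS = ("integer", "double", "boolean", "categorical", "string", "filename", "output")
NUMERIC_KINDS = ("integer", "double")

#: sampling directive modes
MODES = ("constant", "numeric_range", "boolean_set", "categorical_set")


class ManifestError(ValueError):
    """Raised for malformed manifests or invalid sampling specifications."""


@dataclass(frozen=True)
class ParameterSpec:
    """Declaration of a single model parameter.

    Numeric kinds carry inclusive ``min``/``max`` bounds; categorical kinds
    carry an ordered ``items`` list of legal values. ``depends_on`` is parsed
    and retained for documentation but never enforced during sampling.
    """

    name: str
    kind: str
    default: Any
    label: str | None = None
    min: float | None = None
    max: float | None = None
    items: tuple[str, ...] | None = None
    info: str | None = None
    depends_on: str | None = None

    def __post_init__(self) -> None:
        if not self.name or not isinstance(self.name, str):
            raise ManifestError("parameter name must be a non-empty string")
        if self.kind not in KINDS:
            raise ManifestError(
                f"parameter {self.name!r}: unknown kind {self.kind!r} (legal: {KINDS})"
            )
        if self.kind in NUMERIC_KINDS:
            if self.min is None or self.max is None:
                raise ManifestError(f"parameter {self.name!r}: numeric kinds need min and max")
            if not (self.min <= self.default <= self.max):
                raise ManifestError(
                    f"parameter {self.name!r}: default {self.default!r} outside "
                    f"bounds [{self.min}, {self.max}]"
                )
            if self.kind == "integer":
                for fld in ("min", "max", "default"):
                    v = getattr(self, fld)
                    if float(v) != int(v):
                        raise ManifestError(
                            f"parameter {self.name!r}: integer {fld} must be integral, got {v!r}"
                        )
        elif self.kind == "boolean":
            if not isinstance(self.default, bool):
                raise ManifestError(f"parameter {self.name!r}: boolean default must be true/false")
        elif self.kind == "categorical":
            if not self.items:
                raise ManifestError(f"parameter {self.name!r}: categorical needs non-empty items")
            if len(set(self.items)) != len(self.items):
                raise ManifestError(f"parameter {self.name!r}: items must be pairwise distinct")
            if self.default not in self.items:
                raise ManifestError(
                    f"parameter {self.name!r}: default {self.default!r} not among items"
                )

    @property
    def legal_values(self) -> tuple:
        if self.kind == "boolean":
            return (False, True)
        if self.kind == "categorical":
            return tuple(self.items)  # type: ignore[arg-type]
        raise ManifestError(f"parameter {self.name!r} has no enumerable value set")

    def to_dict(self) -> dict:
        d: dict[str, Any] = {"name": self.name, "type": self.kind, "default": self.default}
        for key in ("label", "min", "max", "info", "depends_on"):
            v = getattr(self, key)
            if v is not None:
                d[key] = v
        if self.items is not None:
            d["items"] = list(self.items)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ParameterSpec":
        if "name" not in d:
            raise ManifestError("parameter object missing required field 'name'")
        if "type" not in d:
            raise ManifestError(f"parameter {d.get('name')!r} missing required field 'type'")
        if "default" not in d:
            raise ManifestError(f"parameter {d.get('name')!r} missing required field 'default'")
        items = d.get("items")
        return cls(
            name=d["name"],
            kind=d["type"],
            default=d["default"],
            label=d.get("label"),
            min=d.get("min"),
            max=d.get("max"),
            items=tuple(items) if items is not None else None,
            info=d.get("info"),
            depends_on=d.get("depends_on"),
        )


@dataclass(frozen=True)
class AppManifest:
    """A model app: its name, ordered parameters and declared outputs."""

    app_name: str
    parameters: tuple[ParameterSpec, ...]
    output_tables: tuple[str, ...] = ()
    emits_image: bool = False

    def __post_init__(self) -> None:
        if not self.parameters:
            raise ManifestError(f"manifest {self.app_name!r}: at least one parameter required")
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ManifestError(f"manifest {self.app_name!r}: duplicate parameter names {dupes}")
        if len(set(self.output_tables)) != len(self.output_tables):
            raise ManifestError(f"manifest {self.app_name!r}: duplicate output table names")

    def parameter(self, name: str) -> ParameterSpec:
        for p in self.parameters:
            if p.name == name:
                return p
        raise KeyError(f"no parameter {name!r} in app {self.app_name!r}")

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.parameters)

    def defaults(self) -> dict[str, Any]:
        return {p.name: p.default for p in self.parameters}

    def to_dict(self) -> dict:
        return {
            "app_name": self.app_name,
            "parameters": [p.to_dict() for p in self.parameters],
            "output_tables": list(self.output_tables),
            "emits_image": self.emits_image,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "AppManifest":
        if "app_name" not in d:
            raise ManifestError("manifest missing required field 'app_name'")
        if "parameters" not in d:
            raise ManifestError("manifest missing required field 'parameters'")
        return cls(
            app_name=d["app_name"],
            parameters=tuple(ParameterSpec.from_dict(p) for p in d["parameters"]),
            output_tables=tuple(d.get("output_tables", ())),
            emits_image=bool(d.get("emits_image", False)),
        )


def parse_manifest(document: str | Path | Mapping[str, Any]) -> AppManifest:
    """Parse and validate an app manifest.

    ``document`` may be a JSON string, a path to a JSON file, or an
    already-decoded mapping. All parameter invariants are checked; the first
    violation raises :class:`ManifestError` naming the offending field.
    """
    if isinstance(document, Mapping):
        data = document
    else:
        if isinstance(document, Path) or (
            isinstance(document, str) and not document.lstrip().startswith("{")
        ):
            document = Path(document).read_text()
        try:
            data = json.loads(document)
        except json.JSONDecodeError as exc:
            raise ManifestError(f"manifest is not valid JSON: {exc}") from exc
    if not isinstance(data, Mapping):
        raise ManifestError("manifest document must be a JSON object")
    return AppManifest.from_dict(data)


# ---------------------------------------------------------------------------
# sampling specifications


@dataclass(frozen=True)
class SamplingDirective:
    """How one parameter behaves during a sweep.

    mode=constant holds ``value`` fixed; numeric_range samples uniformly on
    the closed interval [lo, hi]; boolean_set / categorical_set sample
    uniformly over ``enabled_items``.
    """

    parameter: str
    mode: str
    value: Any = None
    lo: float | None = None
    hi: float | None = None
    enabled_items: tuple | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ManifestError(f"directive {self.parameter!r}: unknown mode {self.mode!r}")

    def to_dict(self) -> dict:
        d: dict[str, Any] = {"parameter": self.parameter, "mode": self.mode}
        if self.mode == "constant":
            d["value"] = self.value
        elif self.mode == "numeric_range":
            d["lo"], d["hi"] = self.lo, self.hi
        else:
            d["enabled_items"] = list(self.enabled_items or ())
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SamplingDirective":
        items = d.get("enabled_items")
        return cls(
            parameter=d["parameter"],
            mode=d["mode"],
            value=d.get("value"),
            lo=d.get("lo"),
            hi=d.get("hi"),
            enabled_items=tuple(items) if items is not None else None,
        )


@dataclass(frozen=True)
class SamplingSpec:
    """A complete sweep specification: one directive per manifest parameter."""

    directives: tuple[SamplingDirective, ...]
    n_runs: int = 1
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.n_runs < 0:
            raise ManifestError("n_runs must be non-negative")
        names = [d.parameter for d in self.directives]
        if len(set(names)) != len(names):
            raise ManifestError("duplicate directives for a parameter")

    def directive(self, name: str) -> SamplingDirective:
        for d in self.directives:
            if d.parameter == name:
                return d
        raise KeyError(f"no directive for parameter {name!r}")

    def _replace_directive(self, new: SamplingDirective) -> "SamplingSpec":
        if new.parameter not in {d.parameter for d in self.directives}:
            raise KeyError(f"no directive for parameter {new.parameter!r}")
        updated = tuple(new if d.parameter == new.parameter else d for d in self.directives)
        return replace(self, directives=updated)

    # fluent helpers used throughout the demos and CLI -----------------
    def set_constant(self, name: str, value: Any) -> "SamplingSpec":
        return self._replace_directive(SamplingDirective(name, "constant", value=value))

    def set_range(self, name: str, lo: float, hi: float) -> "SamplingSpec":
        return self._replace_directive(SamplingDirective(name, "numeric_range", lo=lo, hi=hi))

    def set_enabled(self, name: str, items: Iterable) -> "SamplingSpec":
        items = tuple(items)
        mode = "boolean_set" if all(isinstance(i, bool) for i in items) else "categorical_set"
        return self._replace_directive(SamplingDirective(name, mode, enabled_items=items))

    def with_runs(self, n_runs: int, seed: int | None = None,
                  out_dir: str | None = None) -> "SamplingSpec":
        return replace(
            self,
            n_runs=n_runs,
            seed=self.seed if seed is None else seed,
            out_dir=self.out_dir if out_dir is None else out_dir,
        )

    def to_dict(self) -> dict:
        return {
            "directives": [d.to_dict() for d in self.directives],
            "n_runs": self.n_runs,
            "seed": self.seed,
            "out_dir": self.out_dir,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SamplingSpec":
        return cls(
            directives=tuple(SamplingDirective.from_dict(x) for x in d["directives"]),
            n_runs=int(d.get("n_runs", 1)),
            seed=int(d.get("seed", 0)),
            out_dir=d.get("out_dir"),
        )


def load_sampling_spec(path: str | Path) -> SamplingSpec:
    return SamplingSpec.from_dict(json.loads(Path(path).read_text()))


def default_sampling_spec(manifest: AppManifest, n_runs: int = 1, seed: int = 0,
                          out_dir: str | None = None) -> SamplingSpec:
    """All-constant spec: every parameter held at its declared default."""
    directives = tuple(
        SamplingDirective(p.name, "constant", value=p.default) for p in manifest.parameters
    )
    return SamplingSpec(directives=directives, n_runs=n_runs, seed=seed, out_dir=out_dir)


def validate_sampling_spec(manifest: AppManifest, spec: SamplingSpec) -> SamplingSpec:
    """Check every directive against the manifest; return ``spec`` or raise."""
    declared = {p.name for p in manifest.parameters}
    covered = {d.parameter for d in spec.directives}
    if covered != declared:
        missing = sorted(declared - covered)
        extra = sorted(covered - declared)
        raise ManifestError(
            f"sampling spec does not cover the manifest exactly "
            f"(missing: {missing}, unknown: {extra})"
        )
    if spec.n_runs < 1:
        raise ManifestError("n_runs must be >= 1")
    for d in spec.directives:
        p = manifest.parameter(d.parameter)
        if d.mode == "constant":
            _check_constant(p, d.value)
        elif d.mode == "numeric_range":
            if p.kind not in NUMERIC_KINDS:
                raise ManifestError(
                    f"parameter {p.name!r} of kind {p.kind!r} admits no numeric range"
                )
            if d.lo is None or d.hi is None:
                raise ManifestError(f"parameter {p.name!r}: numeric_range needs lo and hi")
            if d.lo > d.hi:
                raise ManifestError(f"parameter {p.name!r}: lo {d.lo} > hi {d.hi}")
            if d.lo < p.min or d.hi > p.max:  # type: ignore[operator]
                raise ManifestError(
                    f"parameter {p.name!r}: range [{d.lo}, {d.hi}] outside manifest "
                    f"bounds [{p.min}, {p.max}]"
                )
        elif d.mode in ("boolean_set", "categorical_set"):
            expected = "boolean_set" if p.kind == "boolean" else "categorical_set"
            if p.kind not in ("boolean", "categorical"):
                raise ManifestError(
                    f"parameter {p.name!r} of kind {p.kind!r} admits no enabled set"
                )
            enabled = d.enabled_items or ()
            if not enabled:
                raise ManifestError(f"parameter {p.name!r}: enabled set is empty")
            if d.mode != expected:
                raise ManifestError(
                    f"parameter {p.name!r}: mode {d.mode!r} does not match kind {p.kind!r}"
                )
            legal = set(p.legal_values)
            bad = [v for v in enabled if v not in legal]
            if bad:
                raise ManifestError(f"parameter {p.name!r}: illegal enabled values {bad}")
            if len(set(enabled)) != len(enabled):
                raise ManifestError(f"parameter {p.name!r}: enabled set has duplicates")
    return spec


def _check_constant(p: ParameterSpec, value: Any) -> None:
    if p.kind in NUMERIC_KINDS:
        if not (p.min <= value <= p.max):  # type: ignore[operator]
            raise ManifestError(
                f"parameter {p.name!r}: constant {value!r} outside bounds [{p.min}, {p.max}]"
            )
        if p.kind == "integer" and float(value) != int(value):
            raise ManifestError(f"parameter {p.name!r}: constant {value!r} is not an integer")
    elif p.kind == "boolean":
        if not isinstance(value, bool):
            raise ManifestError(f"parameter {p.name!r}: constant must be true/false")
    elif p.kind == "categorical":
        if value not in p.legal_values:
            raise ManifestError(f"parameter {p.name!r}: constant {value!r} not among items")
    # string/filename/output: any value passes through
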