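"""Layered INI configuration with strict schema validation.

A run is described by a main (defaults) file plus an optional user file that
overrides only the keys it names.  Every key is checked against the schema:
misspelled or unknown keys fail loudly with the offending name.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

# schema: section -> key -> (type, default).  None defaults mark optional
# paths; required inputs are validated in validate().
SCHEMA: dict[str, dict[str, tuple[type, Any]]] = {
    "data": {
        "expression": (str, None),
        "metadata": (str, None),
        "sample_id_column": (str, "sample_id"),
        "label_attribute": (str, "condition"),
        "second_expression": (str, None),
        "second_metadata": (str, None),
        "delimiter": (str, "\t"),
    },
    "preprocessing": {
        "max_missing_fraction_per_feature": (float, 0.5),
        "max_missing_fraction_per_sample": (float, 0.5),
        "mapping_table": (str, None),
        "collision_policy": (str, "first"),
    },
    "knowledge": {
        "associations": (str, None),
        "gmt": (str, None),
        "edges": (str, None),
        "search_terms": (str, "condition"),
        "min_score": (float, 0.0),
        "aggregation": (str, "max"),
    },
    "selection": {
        "selectors": (str, "anova,weighted_anova"),
        "missing_policy": (str, "epsilon"),
        "epsilon": (float, 0.001),
        "lasso_lambda": (float, 0.1),
        "extension_k_stat": (int, 10),
        "extension_k_kb": (int, 10),
        "n_pathways": (int, 5),
        "n_permutations": (int, 50),
    },
    "evaluation": {
        "classifiers": (str, "naive_bayes,logistic_regression,svm,random_forest,knn3"),
        "cv_k": (int, 10),
        "max_size": (int, 20),
        "cross_dataset": (bool, False),
        "enrichment_library": (str, None),
        "enrichment_alpha": (float, 0.05),
    },
    "run": {
        "seed": (int, 0),
        "output_dir": (str, "results"),
    },
}


@dataclass
class BenchmarkConfig:
    """Validated, effective configuration for one benchmark run."""

    values: dict[str, dict[str, Any]] = field(default_factory=dict)

    def get(self, section: str, key: str) -> Any:
        return self.values[section][key]

    def getlist(self, section: str, key: str) -> list[str]:
        raw = self.values[section][key]
        return [item.strip() for item in str(raw).split(",") if item.strip()]

    def validate(self, selector_names: set[str], classifier_names: set[str]) -> None:
        exp = self.get("data", "expression")
        if exp is None:
            raise ValueError("config: [data] expression is required")
        for section, key in (
            ("data", "expression"),
            ("data", "metadata"),
            ("data", "second_expression"),
            ("data", "second_metadata"),
            ("preprocessing", "mapping_table"),
            ("knowledge", "associations"),
            ("knowledge", "gmt"),
            ("knowledge", "edges"),
            ("evaluation", "enrichment_library"),
        ):
            path = self.get(section, key)
            if path is not None and not Path(path).exists():
                raise ValueError(f"config: [{section}] {key} path not found: {path}")
        unknown_sel = set(self.getlist("selection", "selectors")) - selector_names
        if unknown_sel:
            raise ValueError(f"config: unknown selectors {sorted(unknown_sel)}")
        unknown_clf = set(self.getlist("evaluation", "classifiers")) - classifier_names
        if unknown_clf:
            raise ValueError(f"config: unknown classifiers {sorted(unknown_clf)}")
        if self.get("evaluation", "max_size") < 1:
            raise ValueError("config: [evaluation] max_size must be >= 1")
        if self.get("evaluation", "cv_k") < 2:
            raise ValueError("config: [evaluation] cv_k must be >= 2")

    def snapshot(self, path: str | Path) -> None:
        """Write the effective configuration; it alone reproduces the run."""
        cp = configparser.ConfigParser()
        for section, keys in self.values.items():
            cp[section] = {
                k: repr(v) if v == "\t" else str(v)
                for k, v in keys.items()
                if v is not None
            }
        with open(path, "w") as fh:
            cp.write(fh)


def _coerce(section: str, key: str, raw: str, typ: type) -> Any:
    if typ is bool:
        low = raw.strip().lower()
        if low in ("true", "yes", "1", "on"):
            return True
        if low in ("false", "no", "0", "off"):
            return False
        raise ValueError(f"config: [{section}] {key}: not a boolean: {raw!r}")
    try:
        if raw == "'\\t'":
            return "\t"
        return typ(raw)
    except ValueError:
        raise ValueError(
            f"config: [{section}] {key}: cannot parse {raw!r} as {typ.__name__}"
        ) from None


def _read_ini(path: str | Path) -> dict[str, dict[str, str]]:
    cp = configparser.ConfigParser()
    read = cp.read(path)
    if not read:
        raise FileNotFoundError(path)
    return {s: dict(cp[s]) for s in cp.sections()}


def load_config(
    default_path: str | Path | None = None, user_path: str | Path | None = None
) -> BenchmarkConfig:
    """Merge built-in defaults, an optional defaults file and a user file.

    The user file overrides the defaults key by key; a key that is not in
    the schema is an error naming the key.
    """
    values: dict[str, dict[str, Any]] = {
        section: {k: default for k, (_, default) in keys.items()}
        for section, keys in SCHEMA.items()
    }
    for layer in (default_path, user_path):
        if layer is None:
            continue
        for section, keys in _read_ini(layer).items():
            if section not in SCHEMA:
                raise ValueError(f"config: unknown section [{section}]")
            for key, raw in keys.items():
                if key not in SCHEMA[section]:
                    raise ValueError(f"config: unknown key [{section}] {key!r}")
                typ = SCHEMA[section][key][0]
                values[section][key] = _coerce(section, key, raw, typ)
    return BenchmarkConfig(values)
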