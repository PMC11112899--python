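"""YAML run configuration.

Top-level sections: ``search`` (engine knobs), ``expansion`` (ordered list
of expansion strategies), ``expansion_mode`` ("all" | "first"), ``filter``
(ordered list of filter strategies), ``stock`` (list of {name, path}),
``stop_criteria``, ``scorer``, ``output_path``, ``checkpoint_path`` and
``log_level``.  Unknown top-level keys are rejected so typos fail loudly,
and referenced files must exist at load time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .chem import load_templates
from .policies import (
    CombinedExpansion,
    ConfigError,
    ExpansionStrategy,
    FeasibilityFilter,
    FilterStrategy,
    LookupPrior,
    ReactantCountFilter,
    TemplateExpansion,
    frequency_prior,
)
from .scoring import Scorer, make_scorer
from .search import SearchConfig
from .stock import Stock, StopCriteria, load_stock

_KNOWN_KEYS = {
    "search",
    "expansion",
    "expansion_mode",
    "filter",
    "stock",
    "stop_criteria",
    "scorer",
    "output_path",
    "checkpoint_path",
    "log_level",
}


@dataclass
class RunConfig:
    search: SearchConfig
    expansion: ExpansionStrategy
    filters: list[FilterStrategy]
    stock: Stock
    scorer: Optional[Scorer]
    output_path: Optional[str]
    checkpoint_path: Optional[str]
    log_level: str
    raw: dict = field(default_factory=dict)

    def digest(self) -> str:
        """Stable hash of the effective configuration (guards resume)."""
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()


def _build_expansion(entries: list, mode: str, base: Path) -> ExpansionStrategy:
    if not entries:
        raise ConfigError("config requires at least one expansion strategy")
    strategies: list[ExpansionStrategy] = []
    for i, entry in enumerate(entries):
        kind = entry.get("type", "template")
        if kind != "template":
            raise ConfigError(f"unknown expansion type {kind!r}")
        template_file = entry.get("template_file")
        if not template_file:
            raise ConfigError(f"expansion[{i}]: template_file is required")
        path = base / template_file if not Path(template_file).is_absolute() else Path(template_file)
        if not path.exists():
            raise ConfigError(f"expansion[{i}]: no such file {path}")
        templates = load_templates(path)
        prior_kind = entry.get("prior", "frequency")
        if prior_kind == "frequency":
            prior = frequency_prior(templates)
        elif prior_kind == "lookup":
            table_file = entry.get("table_file")
            if not table_file:
                raise ConfigError(f"expansion[{i}]: lookup prior requires table_file")
            table_path = base / table_file if not Path(table_file).is_absolute() else Path(table_file)
            table = json.loads(Path(table_path).read_text())
            prior = LookupPrior(table, len(templates))
        else:
            raise ConfigError(f"expansion[{i}]: unknown prior {prior_kind!r}")
        strategies.append(
            TemplateExpansion(
                templates,
                prior,
                top_k=int(entry.get("top_k", 50)),
                cutoff_cumulative=float(entry.get("cutoff_cumulative", 0.995)),
                id=entry.get("id", f"expansion-{i}"),
            )
        )
    if len(strategies) == 1:
        return strategies[0]
    return CombinedExpansion(strategies, mode)


def _build_filters(entries: list) -> list[FilterStrategy]:
    filters: list[FilterStrategy] = []
    for entry in entries or []:
        kind = entry.get("type")
        if kind == "reactant_count":
            filters.append(ReactantCountFilter())
        elif kind == "feasibility":
            cutoff = float(entry.get("cutoff", 0.05))
            # without a learned model the proposal prior serves as the score
            filters.append(
                FeasibilityFilter(lambda rxn: min(1.0, max(0.0, rxn.prior)), cutoff)
            )
        else:
            raise ConfigError(f"unknown filter type {kind!r}")
    return filters


def load_config(path) -> RunConfig:
    path = Path(path)
    data = yaml.safe_load(path.read_text()) or {}
    unknown = set(data) - _KNOWN_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
    base = path.parent

    search = SearchConfig(**(data.get("search") or {}))
    mode = data.get("expansion_mode", "all")
    expansion = _build_expansion(data.get("expansion") or [], mode, base)
    filters = _build_filters(data.get("filter"))

    sources = []
    for entry in data.get("stock") or []:
        stock_path = base / entry["path"] if not Path(entry["path"]).is_absolute() else Path(entry["path"])
        if not stock_path.exists():
            raise ConfigError(f"stock: no such file {stock_path}")
        sources.append(load_stock(stock_path, entry.get("name", stock_path.stem)))
    if not sources:
        raise ConfigError("config requires at least one stock source")
    criteria = StopCriteria(**(data.get("stop_criteria") or {}))

    scorer = None
    if data.get("scorer"):
        entry = dict(data["scorer"])
        scorer = make_scorer(entry.pop("name"), **entry.pop("parameters", {}))

    return RunConfig(
        search=search,
        expansion=expansion,
        filters=filters,
        stock=Stock(sources, criteria),
        scorer=scorer,
        output_path=data.get("output_path"),
        checkpoint_path=data.get("checkpoint_path"),
        log_level=data.get("log_level", "INFO"),
        raw=data,
    )
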