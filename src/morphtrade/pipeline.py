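"""Config-driven experiment orchestration.

One experiment reproduces the full comparison layout for a single corpus
(one language/POS): estimate the information profile and tradeoff curve of
the attested ordering, optimize orderings for AUC, sample or enumerate the
baseline ordering families (random and universal-constrained), score every
ordering by AUC and pairwise accuracy against the attested order, and
tabulate root-affix conditional mutual information.  All outputs are plain
TSV/JSON; given identical configuration (including seeds) the emitted
tables are byte-identical across runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Mapping, Sequence

import numpy as np
import yaml

from .corpus_io import Corpus, corpus_summary, read_segmented_tsv
from .evaluate import baseline_quantile, cmi_table, pairwise_accuracy
from .infotheory import (
    auc,
    estimate_entropy_ladder,
    it_profile,
    tradeoff_curve,
)
from .optimize import (
    DEFAULT_ENUMERATION_CAP,
    UniversalConstraints,
    auc_objective,
    enumerate_grammars,
    hill_climb,
    n_grammars,
    sample_random_grammar,
    sample_universal_grammar,
)
from .ordering import (
    SUFFIX,
    OrderingGrammar,
    SlotSchema,
    SlotSpec,
    apply_grammar,
    real_grammar,
    reverse_grammar,
)
from .synthetic import SynthConfig, SynthSlot, generate_corpus

__all__ = [
    "ExperimentConfig",
    "ExperimentError",
    "run_experiment",
    "load_config",
    "schema_from_dict",
    "constraints_from_chains",
    "synth_config_from_dict",
]


class ExperimentError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to run one experiment deterministically."""

    corpus_tsv: str | None = None
    synth: SynthConfig | None = None
    schema: SlotSchema | None = None  # required with corpus_tsv
    constraints: UniversalConstraints | None = None
    estimator: str = "plugin"
    t_max: int | None = None
    n_random_baselines: int = 1000
    n_universal_baselines: int = 1000
    enumeration_cap: int = DEFAULT_ENUMERATION_CAP
    seed: int = 0
    n_restarts: int = 10
    cmi_grammar: str = "optimized"  # or "real"
    cmi_estimator: str = "plugin"  # or "crossfit"
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if (self.corpus_tsv is None) == (self.synth is None):
            raise ValueError("exactly one of corpus_tsv / synth must be given")
        if self.corpus_tsv is not None and self.schema is None:
            raise ValueError("a schema is required with a TSV corpus")
        if self.cmi_grammar not in ("optimized", "real"):
            raise ValueError("cmi_grammar must be 'optimized' or 'real'")
        if self.cmi_estimator not in ("plugin", "crossfit"):
            raise ValueError("cmi_estimator must be 'plugin' or 'crossfit'")


def _fmt(x: float) -> str:
    return format(float(x), ".12g")


def _write_tsv(path: Path, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    lines = ["\t".join(header)]
    for row in rows:
        lines.append(
            "\t".join(_fmt(c) if isinstance(c, float) else str(c) for c in row)
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def run_experiment(config: ExperimentConfig) -> Path:
    """Run the full comparison and write the report directory.

    Artifacts: ``it_profile.tsv`` and ``curve.tsv`` for the attested
    ordering, ``auc_table.tsv`` (real/reverse/optimized plus every
    baseline), ``accuracy_table.tsv`` with quantiles, ``cmi_table.tsv``,
    ``manifest.json`` and ``run.log``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def stage(name: str) -> Callable:
        def run(fn: Callable, *args, **kwargs):
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:
                log_lines.append(f"[{name}] FAILED: {exc}")
                (out / "run.log").write_text("\n".join(log_lines) + "\n")
                raise ExperimentError(f"stage [{name}] failed: {exc}") from exc
            log_lines.append(f"[{name}] ok")
            return result

        return run

    # --- corpus ----------------------------------------------------------
    def load() -> tuple[Corpus, SlotSchema]:
        if config.synth is not None:
            gen = generate_corpus(config.synth)
            return gen.corpus, gen.schema
        assert config.schema is not None
        return read_segmented_tsv(config.corpus_tsv, config.schema), config.schema

    corpus, schema = stage("corpus")(load)
    summary = corpus_summary(corpus)

    # --- orderings -------------------------------------------------------
    real = real_grammar(schema)
    reverse = reverse_grammar(real, schema)
    objective = auc_objective(corpus, t_max=config.t_max, estimator=config.estimator)
    memo: dict[tuple[int, ...], float] = {}

    def auc_of(g: OrderingGrammar) -> float:
        key = g.rank_vector(schema)
        if key not in memo:
            memo[key] = objective(g)
        return memo[key]

    result = stage("optimize")(
        hill_climb,
        corpus,
        schema,
        objective=auc_of,
        seed=config.seed + 1,
        n_restarts=config.n_restarts,
    )
    optimized = result.best_grammar

    # --- baselines -------------------------------------------------------
    def draw_baselines() -> tuple[list[OrderingGrammar], list[OrderingGrammar], bool]:
        exhaustive = n_grammars(schema) <= config.enumeration_cap
        if exhaustive:
            all_g = enumerate_grammars(schema, cap=config.enumeration_cap)
            random_g = all_g
            universal_g = (
                [
                    g
                    for g in all_g
                    if config.constraints.satisfied_by(g, schema)
                ]
                if config.constraints is not None
                else []
            )
        else:
            rng_r = np.random.default_rng(config.seed + 2)
            random_g = [
                sample_random_grammar(schema, rng_r)
                for _ in range(config.n_random_baselines)
            ]
            rng_u = np.random.default_rng(config.seed + 3)
            universal_g = (
                [
                    sample_universal_grammar(schema, config.constraints, rng_u)
                    for _ in range(config.n_universal_baselines)
                ]
                if config.constraints is not None
                else []
            )
        return random_g, universal_g, exhaustive

    random_g, universal_g, exhaustive = stage("baselines")(draw_baselines)

    # --- profile & curve of the attested ordering ------------------------
    def profile_real():
        seqs = apply_grammar(corpus, real)
        t_max = config.t_max or (max(len(s) for s in seqs) + 1)
        ladder = estimate_entropy_ladder(seqs, t_max, config.estimator)
        prof = it_profile(ladder, config.estimator)
        return prof, tradeoff_curve(prof)

    prof, curve = stage("profile")(profile_real)
    _write_tsv(
        out / "it_profile.tsv",
        ["t", "H_t", "I_t"],
        [
            (t, prof.entropy_ladder[t], prof.it_values[t - 1] if t else "")
            for t in range(prof.t_max + 1)
        ],
    )
    _write_tsv(
        out / "curve.tsv",
        ["T", "memory_bits", "excess_surprisal_bits"],
        [(p.T, p.memory_bits, p.excess_surprisal_bits) for p in curve.points],
    )

    # --- AUC table -------------------------------------------------------
    def auc_rows():
        rows = [
            ("real", "real", auc_of(real)),
            ("reverse", "reverse", auc_of(reverse)),
            ("optimized", "optimized", auc_of(optimized)),
        ]
        for i, g in enumerate(random_g):
            rows.append(("random", f"random_{i}", auc_of(g)))
        for i, g in enumerate(universal_g):
            rows.append(("universal", f"universal_{i}", auc_of(g)))
        return rows

    rows = stage("auc_table")(auc_rows)
    _write_tsv(out / "auc_table.tsv", ["family", "id", "auc"], rows)
    auc_random = [r[2] for r in rows if r[0] == "random"]
    auc_universal = [r[2] for r in rows if r[0] == "universal"]

    # --- accuracy table --------------------------------------------------
    def accuracy_rows():
        rows = [("optimized", "optimized", pairwise_accuracy(corpus, optimized, real))]
        for i, g in enumerate(random_g):
            rows.append(("random", f"random_{i}", pairwise_accuracy(corpus, g, real)))
        for i, g in enumerate(universal_g):
            rows.append(
                ("universal", f"universal_{i}", pairwise_accuracy(corpus, g, real))
            )
        return rows

    acc_rows = stage("accuracy_table")(accuracy_rows)
    _write_tsv(out / "accuracy_table.tsv", ["family", "id", "accuracy"], acc_rows)
    acc_optimized = acc_rows[0][2]
    acc_random = [r[2] for r in acc_rows if r[0] == "random"]
    acc_universal = [r[2] for r in acc_rows if r[0] == "universal"]

    # --- CMI table -------------------------------------------------------
    cmi_g = optimized if config.cmi_grammar == "optimized" else real
    by_slot, by_class = stage("cmi_table")(
        cmi_table,
        corpus,
        cmi_g,
        schema,
        estimator=config.cmi_estimator,
        seed=config.seed + 4,
    )
    _write_tsv(
        out / "cmi_table.tsv",
        ["kind", "target", "cmi_bits"],
        [("slot", k, v) for k, v in by_slot.items()]
        + [("class", k, v) for k, v in by_class.items()],
    )

    # --- quantiles & manifest -------------------------------------------
    quantiles: dict[str, float] = {
        "auc_real_vs_random": baseline_quantile(auc_of(real), auc_random, "lower"),
        "auc_optimized_vs_random": baseline_quantile(
            auc_of(optimized), auc_random, "lower"
        ),
        "accuracy_optimized_vs_random": baseline_quantile(
            acc_optimized, acc_random, "higher"
        ),
    }
    if auc_universal:
        quantiles["auc_real_vs_universal"] = baseline_quantile(
            auc_of(real), auc_universal, "lower"
        )
        quantiles["accuracy_optimized_vs_universal"] = baseline_quantile(
            acc_optimized, acc_universal, "higher"
        )

    hashed = {k: v for k, v in sorted(config.__dict__.items()) if k != "out_dir"}
    config_repr = repr(hashed).encode()
    manifest = {
        "config_sha256": hashlib.sha256(config_repr).hexdigest(),
        "seed": config.seed,
        "estimator": config.estimator,
        "n_tokens": summary.n_tokens,
        "n_types": summary.n_types,
        "per_slot_counts": summary.per_slot_counts,
        "n_random_baselines": len(auc_random),
        "n_universal_baselines": len(auc_universal),
        "baselines_exhaustive": exhaustive,
        "optimized_ranks": dict(optimized.ranks),
        "real_ranks": dict(real.ranks),
        "auc": {
            "real": auc_of(real),
            "reverse": auc_of(reverse),
            "optimized": auc_of(optimized),
        },
        "accuracy_optimized": acc_optimized,
        "quantiles": quantiles,
        "s_inf_estimate_bits": curve.s_inf_estimate,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    log_lines.append("[done] all artifacts written")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out


# ---------------------------------------------------------------------------
# config files (YAML or JSON)


def schema_from_dict(spec: Mapping[str, Any]) -> SlotSchema:
    """Build a schema from the config dialect.

    Expected shape: ``{"slots": [{"id", "side", "class", "real_rank"}, ...]}``.
    """
    slots = tuple(
        SlotSpec(
            slot_id=s["id"],
            side=s["side"],
            real_rank=int(s["real_rank"]),
            universal_class=s.get("class", "other"),
        )
        for s in spec["slots"]
    )
    return SlotSchema(slots)


def constraints_from_chains(
    chains: Sequence[Sequence[str]],
) -> UniversalConstraints:
    """Merge ordered class chains into one precedence constraint set."""
    pairs: list[tuple[str, str]] = []
    for chain in chains:
        pairs.extend(UniversalConstraints.from_chain(chain).precedence)
    return UniversalConstraints(tuple(dict.fromkeys(pairs)))


def synth_config_from_dict(spec: Mapping[str, Any]) -> SynthConfig:
    slots = tuple(
        SynthSlot(
            slot_id=s["id"],
            side=s.get("side", SUFFIX),
            n_values=int(s.get("n_values", 2)),
            presence_base=float(s.get("presence_base", 1.0)),
            presence_dependence=float(s.get("presence_dependence", 0.0)),
            value_dependence=float(s.get("value_dependence", 0.0)),
        )
        for s in spec["slots"]
    )
    order = {
        side: tuple(v) for side, v in spec["planted_real_order"].items()
    }
    return SynthConfig(
        n_roots=int(spec["n_roots"]),
        zipf_s=float(spec.get("zipf_s", 1.0)),
        n_classes=int(spec.get("n_classes", 2)),
        slots=slots,
        planted_real_order=order,
        n_tokens=int(spec["n_tokens"]),
        seed=int(spec.get("seed", 0)),
    )


def load_config(path: str | Path) -> ExperimentConfig:
    """Load an experiment config from a YAML (or JSON) file."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    schema = schema_from_dict(raw["schema"]) if "schema" in raw else None
    constraints = (
        constraints_from_chains(raw["constraints"]) if raw.get("constraints") else None
    )
    synth = synth_config_from_dict(raw["synthetic"]) if "synthetic" in raw else None
    return ExperimentConfig(
        corpus_tsv=raw.get("corpus_tsv"),
        synth=synth,
        schema=schema,
        constraints=constraints,
        estimator=raw.get("estimator", "plugin"),
        t_max=raw.get("t_max"),
        n_random_baselines=int(raw.get("n_random_baselines", 1000)),
        n_universal_baselines=int(raw.get("n_universal_baselines", 1000)),
        enumeration_cap=int(raw.get("enumeration_cap", DEFAULT_ENUMERATION_CAP)),
        seed=int(raw.get("seed", 0)),
        n_restarts=int(raw.get("n_restarts", 10)),
        cmi_grammar=raw.get("cmi_grammar", "optimized"),
        cmi_estimator=raw.get("cmi_estimator", "plugin"),
        out_dir=raw.get("out_dir", "results"),
    )
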