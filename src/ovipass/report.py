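"""End-to-end reproduction report.

Reruns the package's two computational engines at study scale and writes
their outputs to a directory:

1. viability curves for geometric lineage ladders of 1..30 lineages (the
   ladders share one common ratio, so communities grow more uneven as they
   gain lineages);
2. minimal all-viable transmission numbers for the built-in six-lineage
   community and the 30-lineage/74-fold stand-in at per-lineage minima
   k in {1, 50, 100};
3. a check of the single-cross-section estimator against the built-in
   compendium of published counts and printed ranges.

Every artifact records the tool version, seed and a config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .datasets import CROSS_SECTION_COMPENDIUM, SIX_LINEAGE_PROFILE, thirty_lineage_profile
from .profiles import make_geometric_profile
from .stereology import total_from_section
from .transmission import (
    SimulationConfig,
    minimal_cells_for_all_viable,
    sweep_frame,
    viability_sweep,
)

__all__ = ["ReportConfig", "reproduce_report", "configure_logging"]

log = logging.getLogger("ovipass")


def configure_logging(verbosity: int = 0) -> None:
    """verbosity: -1 quiet (errors only), 0 info summaries, 1 debug per-grid-point detail."""
    level = {-1: logging.ERROR, 0: logging.INFO}.get(verbosity, logging.DEBUG)
    logging.basicConfig(level=level, format="%(levelname)s %(message)s", force=True)


@dataclass(frozen=True)
class ReportConfig:
    """Settings of a reproduction run; defaults are the study-scale values."""

    seed: int = 0
    iterations: int = 10_000
    max_lineages: int = 30
    curve_grid_max: int = 2_000
    grid_step: int = 20
    min_cells_levels: tuple[int, ...] = (1, 50, 100)
    # common ratio of all ladders = that of the 30-lineage/74-fold ladder
    anchor_lineages: int = 30
    anchor_fold: float = 74.0

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, cfg: ReportConfig) -> None:
    header = f"# ovipass {__version__} seed={cfg.seed} config={cfg.config_hash()}\n"
    path.write_text(header + df.to_csv(index=False))


def _ladder_fold(n_lineages: int, cfg: ReportConfig) -> float:
    # fold-range of an n-lineage ladder sharing the anchor ladder's ratio
    return cfg.anchor_fold ** ((n_lineages - 1) / (cfg.anchor_lineages - 1))


def reproduce_report(outdir: str | Path, config: ReportConfig | None = None) -> dict:
    """Run the full report into ``outdir``; returns a summary dict with a
    ``passed`` flag (exact compendium rows reproduced and simulated minima
    above the expected study-scale thresholds)."""
    cfg = config or ReportConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    (outdir / "run_config.json").write_text(
        json.dumps({"tool": "ovipass", "version": __version__, **asdict(cfg)}, indent=1) + "\n"
    )

    # --- 1. viability curves across community complexity -------------------
    log.info("sweeping viability curves for 1..%d-lineage ladders", cfg.max_lineages)
    profiles, names = [], []
    for n in range(1, cfg.max_lineages + 1):
        profiles.append(make_geometric_profile(n, _ladder_fold(n, cfg)))
        names.append(f"ladder_{n}")
    sim_cfg = SimulationConfig(
        iterations=cfg.iterations,
        cell_grid=tuple(range(1, cfg.curve_grid_max + 1, cfg.grid_step)),
        seed=cfg.seed,
    )
    curves = viability_sweep(profiles, sim_cfg, criterion=1)
    _write_csv(sweep_frame(curves, names), outdir / "viability_curves.csv", cfg)

    # --- 2. minimal transmission numbers -----------------------------------
    communities = {
        "six_lineage_69fold": SIX_LINEAGE_PROFILE,
        "thirty_lineage_74fold": thirty_lineage_profile(),
    }
    rows = []
    minima: dict[tuple[str, int], int | None] = {}
    for name, profile in communities.items():
        for k in cfg.min_cells_levels:
            log.info("searching minimal N: %s, k=%d", name, k)
            result = minimal_cells_for_all_viable(
                profile,
                criterion=k,
                iterations=cfg.iterations,
                grid_step=cfg.grid_step,
                seed=cfg.seed,
            )
            log.debug("  %s k=%d -> %s", name, k, result.to_dict())
            minima[(name, k)] = result.n_min
            rows.append({"profile": name, "min_cells": k, **result.to_dict()})
    single = minimal_cells_for_all_viable(
        make_geometric_profile(1, 1), criterion=1, iterations=cfg.iterations, grid_step=1, seed=cfg.seed
    )
    rows.append({"profile": "single_lineage", "min_cells": 1, **single.to_dict()})
    minimal_df = pd.DataFrame(rows)
    _write_csv(minimal_df, outdir / "minimal_transmission.csv", cfg)

    # --- 3. cross-section estimator check -----------------------------------
    check_rows = []
    for rec in CROSS_SECTION_COMPENDIUM:
        lower = int(total_from_section(rec.n, 0.5))
        upper = int(total_from_section(rec.n, 0.25))
        exact = lower == rec.printed_lower and upper == rec.printed_upper
        check_rows.append(
            {
                "host": rec.host,
                "section_count": rec.n,
                "printed_lower": rec.printed_lower,
                "printed_upper": rec.printed_upper,
                "computed_lower": lower,
                "computed_upper": upper,
                "match": "exact match" if exact else "approximate",
            }
        )
    section_df = pd.DataFrame(check_rows)
    _write_csv(section_df, outdir / "section_estimator_check.csv", cfg)

    # --- summary -------------------------------------------------------------
    exact_hosts = ("Tettigades lacertosa", "Magicicada septendecim")
    exact_ok = all(
        r["match"] == "exact match" for r in check_rows if r["host"] in exact_hosts
    )
    six_k1 = minima.get(("six_lineage_69fold", 1))
    sim_ok = six_k1 is not None and six_k1 > 500 if 1 in cfg.min_cells_levels else True
    summary = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "minimal_transmission": {f"{n}:k={k}": v for (n, k), v in minima.items()},
        "single_lineage_minimum": single.n_min,
        "section_check_exact": exact_ok,
        "passed": bool(exact_ok and sim_ok),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1) + "\n")
    log.info("report written to %s (passed=%s)", outdir, summary["passed"])
    return summary
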