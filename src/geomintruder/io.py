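"""Configuration, file round-trip, and the end-to-end pipeline runner.

All artifacts are plain text: JSON for configs, decks, and reports; CSV
(comma-separated, UTF-8, header row, "." decimal) for trial records and
model predictions; SVG for rendered cards.  Ranks, grid positions, and
Likert scores are 1-based throughout.  Every stochastic stage receives a
sub-seed derived from the run seed, recorded in the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, models, render, synthetic
from .geometry import (
    CardSpec,
    DeckConfig,
    Placement,
    build_deck,
    load_base_shapes,
    sequence_trials,
)
from .synthetic import TRIAL_COLUMNS, GroupParams, default_group_params

__all__ = [
    "RunConfig",
    "write_deck",
    "read_deck",
    "write_trials",
    "read_trials",
    "run_all",
]


@dataclass(frozen=True)
class RunConfig:
    """Top-level run configuration; serializes losslessly to JSON."""

    seed: int = 0
    deck: DeckConfig = field(default_factory=DeckConfig)
    blind: GroupParams | None = None
    blindfolded: GroupParams | None = None
    extractor: str = "edgebank"
    reps: int = 50
    noise_sd: float = 1.0
    tolerance_rel_length: float = 0.01
    tolerance_angle_deg: float = 1.0

    def resolved_groups(self) -> tuple[GroupParams, GroupParams]:
        if self.blind is None or self.blindfolded is None:
            b, f = default_group_params()
            return self.blind or b, self.blindfolded or f
        return self.blind, self.blindfolded

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        if d.get("deck"):
            d["deck"] = DeckConfig(
                **{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in d["deck"].items()
                }
            )
        for g in ("blind", "blindfolded"):
            if d.get(g):
                d[g] = GroupParams(**d[g])
        return cls(**d)


def write_deck(deck: list[CardSpec], path: str | Path, config: DeckConfig) -> None:
    payload = {
        "config": dataclasses.asdict(config),
        "cards": [dataclasses.asdict(c) for c in deck],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_deck(path: str | Path) -> tuple[list[CardSpec], DeckConfig]:
    payload = json.loads(Path(path).read_text())
    cfg = DeckConfig(
        **{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in payload["config"].items()
        }
    )
    cards = [
        CardSpec(
            card_id=c["card_id"],
            family=c["family"],
            deviant_index=c["deviant_index"],
            disposition=c["disposition"],
            placements=tuple(Placement(**p) for p in c["placements"]),
            intruder_position=c["intruder_position"],
        )
        for c in payload["cards"]
    ]
    return cards, cfg


def write_trials(records: pd.DataFrame, path: str | Path) -> None:
    records[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trials file missing columns: {sorted(missing)}")
    for i, row in df.iterrows():
        if not 1 <= row["chosen_position"] <= 6:
            raise ValueError(f"row {i}: chosen_position out of range 1..6")
        if not 1 <= row["confidence"] <= 10:
            raise ValueError(f"row {i}: confidence out of range 1..10")
    df["correct"] = df["correct"].astype(bool)
    return df


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Run the full pipeline: deck -> SVG renders -> model predictions ->
    simulated trials -> analysis report, writing a manifest of seeds and
    file hashes.  Idempotent: identical config gives identical artifacts.

    A failed stage leaves its partial output under ``<outdir>/_partial``
    rather than in place.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    work = outdir / "_partial"
    work.mkdir(exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    sub = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(("deck", "predictions", "trials"), ss.spawn(3))
    }
    families = load_base_shapes()
    fam_map = {f.name: f for f in families}

    deck_cfg = dataclasses.replace(config.deck, rng_seed=sub["deck"])
    deck = build_deck(families, deck_cfg)
    seq = sequence_trials(deck, deck_cfg)
    write_deck(seq, work / "deck.json", deck_cfg)

    svg_dir = work / "cards"
    svg_dir.mkdir(exist_ok=True)
    for card in seq:
        (svg_dir / f"{card.card_id}.svg").write_text(
            render.export_card(card, fam_map)
        )

    tol = models.PropertyTolerance(
        rel_length=config.tolerance_rel_length, angle_deg=config.tolerance_angle_deg
    )
    preds = models.model_predictions(
        families,
        tol=tol,
        config=deck_cfg,
        n_reps=config.reps,
        noise_sd=config.noise_sd,
        seed=sub["predictions"],
    )
    preds.to_csv(work / "predictions.csv", index=False)

    blind, folded = config.resolved_groups()
    records = synthetic.simulate_experiment(blind, folded, seq, seed=sub["trials"])
    write_trials(records, work / "trials.csv")

    te = analysis.tabulate(records, "error")
    tc = analysis.tabulate(records, "confidence")
    err44 = (
        records.assign(err=lambda d: 1.0 - d["correct"].astype(float))
        .groupby(["family", "card_id"], sort=True)["err"]
        .mean()
        .groupby("family")
        .mean()
    )
    slopes_err = analysis.subjectwise_slopes(te, direction="increasing")
    slopes_conf = analysis.subjectwise_slopes(tc, direction="decreasing")
    report = {
        "anova_error": analysis.mixed_anova(te).table.to_dict("records"),
        "anova_confidence": analysis.mixed_anova(tc).table.to_dict("records"),
        "slopes_error": slopes_err.group_stats.to_dict("records"),
        "slopes_error_welch": {
            "t": slopes_err.welch_t,
            "df": slopes_err.welch_df,
            "p": slopes_err.welch_p,
        },
        "slopes_confidence": slopes_conf.group_stats.to_dict("records"),
        "slopes_confidence_welch": {
            "t": slopes_conf.welch_t,
            "df": slopes_conf.welch_df,
            "p": slopes_conf.welch_p,
        },
        "confidence_regression": analysis.confidence_regression(te, tc)
        .reset_index(names="term")
        .to_dict("records"),
        "mean_error_by_family": err44.to_dict(),
    }
    (work / "report.json").write_text(json.dumps(report, indent=1, default=float))

    # promote the completed stage outputs
    final_files = {}
    for p in sorted(work.rglob("*")):
        if p.is_file():
            rel = p.relative_to(work)
            dest = outdir / rel
            dest.parent.mkdir(parents=True, exist_ok=True)
            dest.write_bytes(p.read_bytes())
            final_files[str(rel)] = _sha256(dest)
            p.unlink()
    for d in sorted(work.rglob("*"), reverse=True):
        if d.is_dir():
            d.rmdir()
    work.rmdir()
    manifest = {"seed": config.seed, "sub_seeds": sub, "files": final_files}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
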