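"""Reproducible multi-stage runs: config, logging, condition summaries.

A run is described by a flat key=value config (see ``io.read_flat_config``).
Shared keys::

    outdir=<path>          output directory (created)
    seed=<int>             master seed; every stage derives from it
    stages=<a,b,c>         ordered stage names to execute

Stage names: ``simulate_exofish``, ``exofish``, ``simulate_colonies``,
``colonies``, ``simulate_hacloss``, ``hacloss``, ``simulate_coloc``,
``coloc``, ``report``. Stage parameters are namespaced, e.g.
``exofish.threshold=400``. Every stage logs ``key=value`` lines including
item counts in and out of each filter, and identical config+seed reruns
produce byte-identical CSV outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coloc, focus, hacloss, io, synthetic

logger = logging.getLogger("censtab.pipeline")

STAGES = (
    "simulate_exofish",
    "exofish",
    "simulate_colonies",
    "colonies",
    "simulate_hacloss",
    "hacloss",
    "simulate_coloc",
    "coloc",
    "report",
)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated view over a flat key=value configuration."""

    outdir: Path
    seed: int
    stages: list[str]
    params: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls.from_dict(io.read_flat_config(path))

    @classmethod
    def from_dict(cls, raw: dict[str, str]) -> "RunConfig":
        try:
            outdir = Path(raw["outdir"])
        except KeyError as exc:
            raise ConfigError("config must set outdir") from exc
        seed = int(raw.get("seed", "0"))
        stages = [s.strip() for s in raw.get("stages", "").split(",") if s.strip()]
        unknown = [s for s in stages if s not in STAGES]
        if unknown:
            raise ConfigError(f"unknown stages: {unknown}")
        cfg = cls(outdir=outdir, seed=seed, stages=stages, params=dict(raw))
        cfg.validate()
        return cfg

    def get(self, key: str, default=None, cast=str):
        if key in self.params:
            return cast(self.params[key])
        if default is None:
            raise ConfigError(f"missing required config key {key!r}")
        return default

    def validate(self) -> None:
        if "exofish" in self.stages and self.params.get("exofish.normalize", "0") == "1":
            if "exofish.control_condition" not in self.params:
                raise ConfigError(
                    "exofish.normalize=1 requires exofish.control_condition"
                )
        for key in ("exofish.image", "coloc.stack", "colonies.image",
                    "hacloss.baseline", "hacloss.treated", "hacloss.reference"):
            stage = key.split(".")[0]
            if stage in self.stages and f"simulate_{stage}" not in self.stages:
                if key in self.params and not Path(self.params[key]).exists():
                    raise ConfigError(f"input {self.params[key]} for {key} does not exist")


def _parse_conditions(text: str) -> dict[str, float]:
    """'control:1.0,treated:2.0' -> {'control': 1.0, 'treated': 2.0}."""
    out = {}
    for part in text.split(","):
        name, _, factor = part.partition(":")
        out[name.strip()] = float(factor) if factor else 1.0
    return out


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Execute the configured stages in order; return artifacts by name.

    Any stage failure aborts the run with the stage name in the message.
    """
    config.outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(config.outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("censtab")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    artifacts: dict[str, object] = {}
    logger.info("run start seed=%d stages=%s", config.seed, ",".join(config.stages))
    try:
        for stage in config.stages:
            logger.info("stage=%s status=start", stage)
            try:
                _STAGE_FUNCS[stage](config, artifacts)
            except Exception as exc:
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
            logger.info("stage=%s status=done", stage)
    finally:
        root.removeHandler(handler)
        handler.close()
    return artifacts


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_simulate_exofish(cfg: RunConfig, art: dict) -> None:
    conditions = _parse_conditions(cfg.get("exofish.conditions", "control:1.0"))
    base_amp = cfg.get("exofish.amplitude", 800.0, float)
    for i, (cond, factor) in enumerate(sorted(conditions.items())):
        spec = synthetic.ImageFieldSpec(
            n_cells=cfg.get("exofish.n_cells", 20, int),
            foci_per_cell=cfg.get("exofish.foci_per_cell", 6, int),
            focus_amplitude=base_amp * factor,
            seed=cfg.seed + i,
        )
        image, labels, truth = synthetic.make_exofish_field(spec)
        io.save_image(cfg.outdir / f"field_{cond}.tif", image.astype(np.float32), "YX")
        io.save_image(cfg.outdir / f"labels_{cond}.tif", labels, "YX")
        io.save_table(cfg.outdir / f"truth_{cond}.csv", truth)
    art["exofish_conditions"] = sorted(conditions)


def _stage_exofish(cfg: RunConfig, art: dict) -> None:
    params = focus.FocusDetectionParams(
        threshold=cfg.get("exofish.threshold", 400.0, float),
        min_area=cfg.get("exofish.min_area", 2, int),
        box_size=cfg.get("exofish.box_size", 14, int),
    )
    conditions = art.get("exofish_conditions")
    if conditions is None:
        conditions = [
            c.strip() for c in cfg.get("exofish.analyze_conditions", "control").split(",")
        ]
    frames = []
    for cond in conditions:
        image, _ = io.load_image(cfg.outdir / f"field_{cond}.tif")
        labels, _ = io.load_image(cfg.outdir / f"labels_{cond}.tif")
        df = focus.quantify_cells(image.astype(float), labels, params)
        logger.info(
            "stage=exofish condition=%s cells_in=%d cells_kept=%d cells_excluded=%d",
            cond, len(df) + len(df.attrs["skipped"]), len(df), len(df.attrs["skipped"]),
        )
        df.insert(0, "condition", cond)
        frames.append(df)
    per_cell = pd.concat(frames, ignore_index=True)
    if cfg.params.get("exofish.normalize", "0") == "1":
        control = cfg.get("exofish.control_condition")
        per_cell["signal_norm"] = focus.normalize_to_control(
            per_cell["signal_sum"], per_cell["condition"], control
        ).to_numpy()
    io.save_table(cfg.outdir / "exofish_per_cell.csv", per_cell)
    art["exofish_per_cell"] = per_cell


def _stage_simulate_colonies(cfg: RunConfig, art: dict) -> None:
    image, truth = synthetic.make_colony_plate(
        n_disks=cfg.get("colonies.n_disks", 10, int),
        disk_radius=cfg.get("colonies.disk_radius", 12.0, float),
        thin_streak_length=(
            cfg.get("colonies.streak_length", 0, int) or None
        ),
        seed=cfg.seed,
    )
    io.save_image(cfg.outdir / "plate.tif", image, "YX")
    art["colonies_truth"] = truth


def _stage_colonies(cfg: RunConfig, art: dict) -> None:
    image, _ = io.load_image(cfg.params.get("colonies.image", cfg.outdir / "plate.tif"))
    params = focus.ColonyCountParams(
        threshold=cfg.get("colonies.threshold", 128.0, float)
    )
    count, table = focus.count_colonies(image, params)
    logger.info(
        "stage=colonies objects_in=%d kept=%d excluded=%d",
        len(table), count, len(table) - count,
    )
    io.save_table(cfg.outdir / "colonies.csv", table)
    art["colony_count"] = count


def _stage_simulate_hacloss(cfg: RunConfig, art: dict) -> None:
    di = cfg.get("hacloss.true_di", 3.33, float)
    p0 = cfg.get("hacloss.p0", 0.9, float)
    p_si = cfg.get("hacloss.p_si", 0.6, float)
    n_events = cfg.get("hacloss.n_events", 20000, int)
    dye_spec = synthetic.DyeDilutionSpec.from_division_index(
        di, n_events=n_events, seed=cfg.seed
    )
    dye, dye_truth = synthetic.make_dye_dilution(dye_spec)
    ref_spec = synthetic.DyeDilutionSpec(
        n_events=n_events, generation_weights=(1.0,), seed=cfg.seed + 1
    )
    ref, _ = synthetic.make_dye_dilution(ref_spec)
    base, _ = synthetic.make_hac_flow(
        synthetic.HacFlowSpec(gfp_positive_fraction=p0, seed=cfg.seed + 2)
    )
    treated, _ = synthetic.make_hac_flow(
        synthetic.HacFlowSpec(gfp_positive_fraction=p_si, seed=cfg.seed + 3)
    )
    for name, df in (
        ("dye_treated", dye), ("dye_reference", ref),
        ("flow_baseline", base), ("flow_treated", treated),
    ):
        io.save_table(cfg.outdir / f"{name}.csv", df)
    art["hacloss_truth"] = {"di": dye_truth, "p0": p0, "p_si": p_si}


def _stage_hacloss(cfg: RunConfig, art: dict) -> None:
    base = io.load_table(cfg.params.get("hacloss.baseline", cfg.outdir / "flow_baseline.csv"))
    treated = io.load_table(cfg.params.get("hacloss.treated", cfg.outdir / "flow_treated.csv"))
    dye = io.load_table(cfg.params.get("hacloss.dye", cfg.outdir / "dye_treated.csv"))
    ref = io.load_table(cfg.params.get("hacloss.reference", cfg.outdir / "dye_reference.csv"))
    fit = hacloss.fit_dye_dilution(
        dye, ref,
        n_peaks=cfg.get("hacloss.n_peaks", 7, int),
        ratio=cfg.get("hacloss.peak_ratio", 0.5, float),
    )
    definition = cfg.get("hacloss.di_definition", "precursor_weighted")
    di = fit.division_index(definition)
    p0 = hacloss.gfp_positive_fraction(hacloss.gate_live(base))
    p_si = hacloss.gfp_positive_fraction(hacloss.gate_live(treated))
    result = hacloss.hac_loss_rate(p_si, p0, di.value)
    out = pd.DataFrame(
        [{"P0": result.p0, "P_si": result.p_si, "n": result.n, "R": result.rate,
          "di_definition": definition}]
    )
    io.save_table(cfg.outdir / "hacloss.csv", out)
    (cfg.outdir / "hacloss_fit.txt").write_text(fit.summary() + "\n")
    logger.info(
        "stage=hacloss P0=%.6g P_si=%.6g n=%.6g R=%.6g", result.p0, result.p_si,
        result.n, result.rate,
    )
    art["hacloss_result"] = result


def _default_stack_spec(cfg: RunConfig, n_overlap: int, seed: int) -> synthetic.StackSpec:
    channels = (
        synthetic.ChannelSpec("cenpb", n_spots=cfg.get("coloc.ref_spots", 3, int),
                              spot_radius_um=0.25, amplitude=1500.0),
        synthetic.ChannelSpec("halo", n_spots=cfg.get("coloc.partner_spots", 3, int),
                              spot_radius_um=0.25, amplitude=1500.0),
    )
    overlaps = tuple(
        synthetic.EngineeredOverlap("cenpb", "halo", 0.5) for _ in range(n_overlap)
    )
    return synthetic.StackSpec(
        n_nuclei=cfg.get("coloc.n_nuclei", 3, int),
        channels=channels,
        engineered_overlaps=overlaps,
        seed=seed,
    )


def _stage_simulate_coloc(cfg: RunConfig, art: dict) -> None:
    spec = _default_stack_spec(cfg, cfg.get("coloc.engineered_events", 2, int), cfg.seed)
    channels, truth = synthetic.make_stack(spec)
    stack = np.stack([channels[name] for name in ("dna", "cenpb", "halo")])
    io.save_image(
        cfg.outdir / "stack.tif", stack.astype(np.float32), "CZYX",
        channel_names=["dna", "cenpb", "halo"],
        voxel_size_zyx=list(spec.voxel_size_zyx),
    )
    art["coloc_truth"] = truth


def _stage_coloc(cfg: RunConfig, art: dict) -> None:
    arr, meta = io.load_image(cfg.params.get("coloc.stack", cfg.outdir / "stack.tif"))
    names = meta.get("channel_names", [f"ch{i}" for i in range(arr.shape[0])])
    voxel = tuple(meta.get("voxel_size_zyx", (10.65 / 15, 0.1, 0.1)))
    stack = coloc.VoxelStack(
        channels={n: arr[i].astype(float) for i, n in enumerate(names)},
        voxel_size_zyx=voxel,
    )
    mask, masked = coloc.segment_nuclei_3d(stack, cfg.get("coloc.dna_channel", "dna"))
    records = coloc.individualize_nuclei(masked, mask)
    kept, excluded = coloc.qc_filter(
        records, area_limit_um2=cfg.get("coloc.area_limit", 300.0, float)
    )
    selected = coloc.select_nuclei(
        kept, n=cfg.get("coloc.n_select", 100, int), seed=cfg.seed
    )
    logger.info(
        "stage=coloc nuclei_in=%d kept=%d excluded=%d selected=%d",
        len(records), len(kept), len(excluded), len(selected),
    )
    ref = cfg.get("coloc.reference_channel", "cenpb")
    par = cfg.get("coloc.partner_channel", "halo")
    sp = coloc.SpotSegmentationParams(
        smooth_sigma=cfg.get("coloc.smooth_sigma", 1.0, float),
        seed_threshold=cfg.get("coloc.seed_threshold", 600.0, float),
        include_threshold=cfg.get("coloc.include_threshold", 350.0, float),
    )
    summary, events = coloc.analyze_cohort(
        selected, ref, par, {ref: sp, par: sp}, voxel,
        min_overlap=cfg.get("coloc.min_overlap", 0.10, float),
    )
    ev_rows = [
        {"nucleus_id": nid, "reference_spot": e.reference_spot_id,
         "partner_spot": e.partner_spot_id, "fraction": e.overlap_fraction}
        for nid, evs in sorted(events.items()) for e in evs
    ]
    io.save_table(cfg.outdir / "coloc_events.csv",
                  pd.DataFrame(ev_rows, columns=["nucleus_id", "reference_spot",
                                                 "partner_spot", "fraction"]))
    io.save_table(cfg.outdir / "coloc_per_nucleus.csv", summary.per_nucleus_events)
    io.save_table(
        cfg.outdir / "coloc_excluded.csv",
        pd.DataFrame(
            [{"nucleus_id": r.nucleus_id, "reasons": ";".join(sorted(r.qc_flags))}
             for r in excluded],
            columns=["nucleus_id", "reasons"],
        ),
    )
    io.save_table(
        cfg.outdir / "coloc_summary.csv",
        pd.DataFrame([{
            "n_nuclei": summary.n_nuclei,
            "fraction_with_event": summary.fraction_with_event,
            "mean_events_per_nucleus": summary.mean_events_per_nucleus,
        }]),
    )
    art["coloc_summary"] = summary


def _stage_report(cfg: RunConfig, art: dict) -> None:
    per_cell = art.get("exofish_per_cell")
    if per_cell is None:
        path = cfg.outdir / "exofish_per_cell.csv"
        if not path.exists():
            raise ConfigError("report stage needs exofish per-cell output")
        per_cell = io.load_table(path)
    control = cfg.params.get("exofish.control_condition")
    table = condition_table(per_cell, value="signal_sum", control_condition=control)
    io.save_table(cfg.outdir / "condition_summary.csv", table)
    art["condition_summary"] = table


_STAGE_FUNCS = {
    "simulate_exofish": _stage_simulate_exofish,
    "exofish": _stage_exofish,
    "simulate_colonies": _stage_simulate_colonies,
    "colonies": _stage_colonies,
    "simulate_hacloss": _stage_simulate_hacloss,
    "hacloss": _stage_hacloss,
    "simulate_coloc": _stage_simulate_coloc,
    "coloc": _stage_coloc,
    "report": _stage_report,
}


# ---------------------------------------------------------------------------
# Condition summaries
# ---------------------------------------------------------------------------

def condition_table(
    per_cell: pd.DataFrame,
    value: str = "signal_sum",
    condition: str = "condition",
    replicate: str | None = None,
    control_condition: str | None = None,
) -> pd.DataFrame:
    """Per-condition (and per-replicate) means of a per-cell readout.

    Pooled per-cell statistics and replicate means are reported separately so
    downstream statistics can operate on replicate means, the unit of
    inference in multi-experiment designs. With ``control_condition`` set, a
    normalized column divides condition means by the control's mean (the
    control maps to exactly 1).
    """
    if condition not in per_cell.columns:
        raise ValueError(f"missing condition column {condition!r}")
    unknown = per_cell[per_cell[condition].isna()]
    if len(unknown):
        raise ValueError("rows with missing condition labels")
    group_cols = [condition] + ([replicate] if replicate else [])
    rows = []
    for cond, sub in per_cell.groupby(condition, sort=True):
        row = {
            "condition": cond,
            "n": len(sub),
            "mean": sub[value].mean(),
            "sd": sub[value].std(ddof=1) if len(sub) > 1 else 0.0,
        }
        if replicate:
            rep_means = sub.groupby(replicate)[value].mean()
            row["replicate_means"] = ";".join(f"{m:.6g}" for m in rep_means)
        rows.append(row)
    table = pd.DataFrame(rows)
    if control_condition is not None:
        ctrl = table.loc[table["condition"] == control_condition, "mean"]
        if len(ctrl) == 0:
            raise ValueError(f"control condition {control_condition!r} absent")
        if float(ctrl.iloc[0]) == 0:
            raise ValueError("control mean is zero; cannot normalize")
        table["mean_norm"] = table["mean"] / float(ctrl.iloc[0])
    return table
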