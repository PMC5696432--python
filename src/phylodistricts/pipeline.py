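"""End-to-end analysis runner: from (tree, community, coordinates) to
alpha/beta diversity tables, permutation tests, ordinations, endemism
metrics and interpolated surfaces.

The stages run in the order the analysis requires: reconcile tree and
matrix; per-plot Fisher's alpha, Faith PD and ses.MPD; TBD, PBD and
null-PBD matrices; Mantel correlations (TBD~PBD and TBD~null-PBD); NMDS on
both matrices; MRPP on user-supplied (or provisional k-medoids) district
labels; WPE, AED and IAC; per-plot mean dissimilarities; and Loess
surfaces for the six mapped quantities (TBD, PBD, null-PBD, WPE, IAC and
the plot-mean AED).  Every output is a CSV or JSON file, and a manifest
records the full configuration, seeds and a config hash so a run can be
reproduced exactly.  No multiple-testing correction is applied across the
two Mantel tests; both p-values are reported as-is.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alpha import faith_pd_table, ses_mpd
from .beta import (
    mean_row_dissimilarity,
    null_phylosor,
    phylosor_matrix,
    sorenson_matrix,
)
from .community import (
    align_tree_matrix,
    fisher_alpha,
    read_community,
    read_coordinates,
)
from .endemism import endemism_table
from .ordination import k_medoids, mantel, mrpp, nmds
from .spatial import GridSpec, interpolate_metric_surface
from .tree import read_newick

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs and tuning knobs for a full analysis run."""

    tree_path: str
    community_path: str
    coords_path: str | None = None
    groups_path: str | None = None  # CSV: plot_id, group
    output_dir: str = "results"
    n_null: int = 999
    n_perm: int = 999
    nmds_starts: int = 1000
    n_groups: int = 3
    cell_size: float = 0.5
    loess_span: float = 0.75
    loess_degree: int = 2
    seed: int = 0

    def __post_init__(self):
        if min(self.n_null, self.n_perm, self.nmds_starts, self.n_groups) < 1:
            raise ValueError("counts must be positive")
        if not 0 < self.loess_span <= 1:
            raise ValueError("loess span must be in (0, 1]")
        if self.loess_degree not in (1, 2):
            raise ValueError("loess degree must be 1 or 2")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(manifest: dict, name: str):
    manifest["stages"].append(name)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis; returns the output directory.

    A stage failure aborts with the stage name attached; outputs written
    before the failure are retained.  If no coordinates file is given the
    spatial stage is skipped and flagged in the manifest.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stages": [],
        "outputs": [],
        "notes": [
            "no multiple-testing correction across the two Mantel tests",
        ],
    }
    seeds = np.random.SeedSequence(config.seed).generate_state(8)

    def save_df(df, name, **kw):
        path = out / name
        df.to_csv(path, **kw)
        manifest["outputs"].append(name)
        return path

    def save_json(obj, name):
        path = out / name
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True)
            fh.write("\n")
        manifest["outputs"].append(name)

    current = "load-inputs"
    try:
        tree = read_newick(config.tree_path)
        cm = read_community(config.community_path)
        coords = (
            read_coordinates(config.coords_path) if config.coords_path else None
        )

        current = "align"
        tree, cm, report = align_tree_matrix(tree, cm)
        manifest["alignment"] = {
            "dropped_species": report.dropped_species,
            "pruned_tips": report.pruned_tips,
            "n_plots": len(cm.plot_ids),
            "n_species": len(cm.species),
        }
        _stage(manifest, current)

        current = "alpha-diversity"
        alpha_df = pd.DataFrame(
            {"N": cm.totals, "S": cm.richness},
            index=pd.Index(cm.plot_ids, name="plot_id"),
        )
        alpha_df["fisher_alpha"] = [
            fisher_alpha(s, n) if 1 <= s < n else np.nan
            for s, n in zip(alpha_df["S"], alpha_df["N"])
        ]
        alpha_df["PD"] = faith_pd_table(tree, cm)
        distances = tree.distance_matrix()
        ses = ses_mpd(
            tree, cm, n_null=config.n_null, seed=int(seeds[0]), distances=distances
        )
        alpha_df = alpha_df.join(ses.add_prefix("mpd_"))
        save_df(alpha_df, "alpha_diversity.csv")
        _stage(manifest, current)

        current = "beta-diversity"
        tbd = sorenson_matrix(cm)
        pbd = phylosor_matrix(tree, cm)
        nullres = null_phylosor(tree, cm, n_null=config.n_null, seed=int(seeds[1]))
        save_df(tbd.to_dataframe(), "tbd.csv", index_label="plot_id")
        save_df(pbd.to_dataframe(), "pbd.csv", index_label="plot_id")
        save_df(
            nullres.expected.to_dataframe(), "null_pbd_expected.csv",
            index_label="plot_id",
        )
        save_df(
            nullres.deviation_dataframe(), "null_pbd_deviation.csv",
            index_label="plot_id",
        )
        _stage(manifest, current)

        current = "mantel"
        m1 = mantel(tbd, pbd, n_perm=config.n_perm, seed=int(seeds[2]))
        m2 = mantel(tbd, nullres.expected, n_perm=config.n_perm, seed=int(seeds[3]))
        save_json(
            {
                "TBD~PBD": vars(m1),
                "TBD~nullPBD": vars(m2),
            },
            "mantel.json",
        )
        _stage(manifest, current)

        current = "nmds"
        ord_tbd = nmds(tbd, n_starts=config.nmds_starts, seed=int(seeds[4]))
        ord_pbd = nmds(pbd, n_starts=config.nmds_starts, seed=int(seeds[5]))
        ord_tbd.to_csv(out / "nmds_tbd.csv")
        ord_pbd.to_csv(out / "nmds_pbd.csv")
        manifest["outputs"] += ["nmds_tbd.csv", "nmds_pbd.csv"]
        manifest["nmds_stress"] = {"TBD": ord_tbd.stress, "PBD": ord_pbd.stress}
        _stage(manifest, current)

        current = "mrpp"
        if config.groups_path:
            gdf = pd.read_csv(config.groups_path)
            groups = dict(zip(gdf.iloc[:, 0].astype(str), gdf.iloc[:, 1]))
            manifest["groups"] = "user-supplied"
        else:
            groups = k_medoids(tbd, k=config.n_groups).to_dict()
            manifest["groups"] = (
                "derived (k-medoids on TBD; provisional, not analyst-confirmed)"
            )
        mrpp_tbd = mrpp(tbd, groups, n_perm=config.n_perm, seed=int(seeds[6]))
        mrpp_pbd = mrpp(pbd, groups, n_perm=config.n_perm, seed=int(seeds[7]))
        save_json(
            {"TBD": mrpp_tbd.to_dict(), "PBD": mrpp_pbd.to_dict(),
             "groups": {str(k): str(v) for k, v in groups.items()}},
            "mrpp.json",
        )
        _stage(manifest, current)

        current = "endemism"
        tables = endemism_table(tree, cm)
        save_df(tables.per_plot, "endemism.csv", index_label="plot_id")
        save_df(tables.per_species, "aed.csv", index=False)
        _stage(manifest, current)

        current = "mean-dissimilarity"
        mean_tbd = mean_row_dissimilarity(tbd)
        mean_pbd = mean_row_dissimilarity(pbd)
        mean_null = mean_row_dissimilarity(nullres.expected)
        means = pd.concat([mean_tbd, mean_pbd, mean_null], axis=1)
        save_df(means, "mean_dissimilarity.csv")
        _stage(manifest, current)

        current = "surfaces"
        if coords is None:
            manifest["spatial"] = "skipped: no coordinates supplied"
        else:
            spec = GridSpec.from_points(
                coords["lon"].to_numpy(),
                coords["lat"].to_numpy(),
                cell_size=config.cell_size,
            )
            aed_mean = (
                tables.per_species.groupby("plot_id")["AED"].mean().rename("AED_mean")
            )
            metrics = {
                "tbd": mean_tbd,
                "pbd": mean_pbd,
                "null_pbd": mean_null,
                "wpe": tables.per_plot["WPE"],
                "iac": tables.per_plot["IAC"],
                "aed": aed_mean,
            }
            surf_names = []
            for key, series in metrics.items():
                surf = interpolate_metric_surface(
                    series,
                    coords,
                    spec=spec,
                    span=config.loess_span,
                    degree=config.loess_degree,
                    label=key,
                )
                name = f"surface_{key}.csv"
                surf.to_csv(out / name)
                surf_names.append(name)
            manifest["outputs"] += surf_names
            manifest["spatial"] = {
                "cell_size": config.cell_size,
                "span": config.loess_span,
                "degree": config.loess_degree,
                "surfaces": surf_names,
            }
        _stage(manifest, current)
    except Exception as exc:
        manifest["failed_stage"] = current
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
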