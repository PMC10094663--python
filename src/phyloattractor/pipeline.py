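"""End-to-end orchestration: one TOML config, staged outputs, a manifest.

Stages run in dependency order - network, centrality, walk sweep,
expression/folds, stratum profiles + ANOM, GO enrichment - each writing a
TSV under the run's output directory.  Real numbers are written with fixed
9-decimal formatting so byte-level reproducibility is meaningful; a JSON
manifest records the config, per-stage output paths, row counts and sha256
digests.  One master seed is given in the config and per-stage seeds are
derived by stable hashing of (master seed, stage name), so identical config
and inputs give byte-identical outputs.

Config schema (TOML), all sections optional except [run]::

    [run]        seed = 0, out_dir = "out"
    [network]    source = "synthetic" | "files"
                 # synthetic: n_per_stratum, model, m, divergence
                 # files: edges, strata (paths), threshold
    [walk]       lengths = [5, 30, 100, 1000], repeats = 10000, start_stratum = 17
    [expression] source = "synthetic" | "files"
                 # synthetic: n_cells, sigma, delta_start, delta_slope
                 # files: matrix, groups, group_a, group_b  (or folds = path)
    [profile]    bins = [[1,1],[2,2],[3,3],[4,6],[7,9],[10,17]]
    [enrichment] n_terms, annotation_rate, n_planted, planted_shift,
                 min_size, n_samples   # or go_edges/go_annot paths
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import centrality as centrality_mod
from . import enrichment as enrichment_mod
from . import expression as expression_mod
from . import netio, synth, walker

try:  # Python >= 3.11
    import tomllib
except ModuleNotFoundError:  # pragma: no cover
    import tomli as tomllib  # type: ignore[no-redef]

logger = logging.getLogger("phyloattractor")

FLOAT_FMT = "%.9f"


def derive_seed(master: int, stage: str) -> int:
    """Stable stage seed: sha256(master:stage) reduced below 2**31."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:8], "big") % (2**31)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    input_digests: dict[str, str] = field(default_factory=dict)
    stages: dict[str, dict] = field(default_factory=dict)
    completed: bool = False

    def record(self, stage: str, outputs: dict[str, Path], extra: dict | None = None) -> None:
        entry: dict = {"outputs": {}}
        for name, path in outputs.items():
            n_rows = max(0, len(path.read_text().splitlines()) - 1)
            entry["outputs"][name] = {
                "path": str(path),
                "rows": n_rows,
                "sha256": _digest(path),
            }
        if extra:
            entry.update(extra)
        self.stages[stage] = entry

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "seed": self.seed,
                "version": self.version,
                "input_digests": self.input_digests,
                "stages": self.stages,
                "completed": self.completed,
            },
            indent=2,
            sort_keys=True,
        )


def _load_network(cfg: dict, seed: int, out: Path) -> tuple[netio.InteractionNetwork, netio.StratumMap]:
    sec = cfg.get("network", {})
    if sec.get("source", "synthetic") == "files":
        net = netio.read_network(sec["edges"], threshold=float(sec.get("threshold", 0.5)))
        smap = netio.read_stratum_map(sec["strata"])
    else:
        gen = synth.NetworkGenConfig(
            n_per_stratum=list(sec.get("n_per_stratum", [30] * netio.N_STRATA)),
            model=sec.get("model", "pa"),
            m=int(sec.get("m", 3)),
            divergence=float(sec.get("divergence", 0.3)),
            seed=derive_seed(seed, "network"),
        )
        net, smap = synth.gen_network(gen)
    netio.write_network(net, out / "edges.tsv")
    netio.write_stratum_map(smap, out / "strata.tsv")
    return net, smap


def _expression_folds(cfg: dict, seed: int, smap: netio.StratumMap) -> expression_mod.FoldTable:
    sec = cfg.get("expression", {})
    if sec.get("source", "synthetic") == "files":
        if "folds" in sec:
            return expression_mod.read_fold_table(sec["folds"])
        values = pd.read_csv(sec["matrix"], sep="\t", index_col=0)
        groups = pd.read_csv(sec["groups"], sep="\t", index_col=0).iloc[:, 0]
        mat = expression_mod.ExpressionMatrix(values=values, groups=groups)
        mat = expression_mod.quantile_normalize(mat, data_kind=sec.get("data_kind", "counts"))
        return expression_mod.group_fold(
            mat, sec.get("group_a", "group_a"), sec.get("group_b", "group_b")
        )
    start = float(sec.get("delta_start", 0.5))
    slope = float(sec.get("delta_slope", -0.03))
    gen = synth.ExpressionGenConfig(
        delta=lambda s: start + slope * (s - 1),
        sigma=float(sec.get("sigma", 0.5)),
        n_cells=int(sec.get("n_cells", 50)),
        seed=derive_seed(seed, "expression"),
    )
    mat = synth.gen_expression(gen, smap)
    mat = expression_mod.quantile_normalize(mat, data_kind="counts")
    return expression_mod.group_fold(mat, "group_a", "group_b")


def run_all(config_path: str | Path) -> RunManifest:
    """Execute the full analysis described by a TOML config file."""
    config_path = Path(config_path)
    with open(config_path, "rb") as fh:
        cfg = tomllib.load(fh)
    run = cfg.get("run", {})
    seed = int(run.get("seed", 0))
    out = Path(run.get("out_dir", "out"))

    # fail before any stage runs if declared inputs are missing
    for sec in ("network", "expression", "enrichment"):
        s = cfg.get(sec, {})
        for key in ("edges", "strata", "matrix", "groups", "folds", "go_edges", "go_annot"):
            if key in s and not Path(s[key]).exists():
                raise FileNotFoundError(f"[{sec}] {key} = {s[key]} does not exist")

    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=seed, version=__version__)
    for sec in ("network", "expression", "enrichment"):
        s = cfg.get(sec, {})
        for key in ("edges", "strata", "matrix", "groups", "folds", "go_edges", "go_annot"):
            if key in s:
                manifest.input_digests[f"{sec}.{key}"] = _digest(Path(s[key]))

    try:
        # --- network ------------------------------------------------------
        net, smap = _load_network(cfg, seed, out)
        manifest.record(
            "network",
            {"edges": out / "edges.tsv", "strata": out / "strata.tsv"},
            {"n_nodes": net.n_nodes(), "n_edges": net.n_edges()},
        )

        # --- centrality ---------------------------------------------------
        profile = centrality_mod.compute_profile(net, smap)
        _write_tsv(profile.per_node, out / "centrality_nodes.tsv")
        _write_tsv(profile.per_stratum, out / "centrality_strata.tsv")
        manifest.record(
            "centrality",
            {"per_node": out / "centrality_nodes.tsv", "per_stratum": out / "centrality_strata.tsv"},
            {"n_unmapped": profile.n_unmapped},
        )

        # --- walks --------------------------------------------------------
        wsec = cfg.get("walk", {})
        lengths = [int(x) for x in wsec.get("lengths", [5, 30, 100, 1000])]
        wcfg = walker.WalkConfig(
            n_repeats=int(wsec.get("repeats", 10_000)),
            walk_length=max(lengths),
            start_stratum=int(wsec.get("start_stratum", 17)),
            seed=derive_seed(seed, "walk"),
        )
        dists, tvs = walker.length_sweep(net, smap, lengths, wcfg)
        rows = []
        for length, d in zip(lengths, dists):
            for s in range(1, netio.N_STRATA + 1):
                rows.append(
                    {
                        "length": length,
                        "stratum": s,
                        "raw_count": d.raw_counts[s],
                        "normalized_frequency": d.normalized[s],
                    }
                )
        _write_tsv(pd.DataFrame(rows), out / "walk_endpoints.tsv", index=False)
        manifest.record(
            "walk",
            {"endpoints": out / "walk_endpoints.tsv"},
            {"tv_successive": [round(t, 9) for t in tvs]},
        )

        # --- expression folds ----------------------------------------------
        folds = _expression_folds(cfg, seed, smap)
        _write_tsv(folds.table, out / "folds.tsv")
        manifest.record("folds", {"folds": out / "folds.tsv"},
                        {"orientation": f"{folds.group_a} - {folds.group_b}"})

        # --- stratum profile + ANOM ----------------------------------------
        psec = cfg.get("profile", {})
        bins = [tuple(b) for b in psec.get("bins", expression_mod.DEFAULT_BINS)]
        prof = expression_mod.stratum_profile(folds.folds, smap, bins=bins)
        assert isinstance(prof, expression_mod.StratumProfile)
        _write_tsv(prof.table, out / "fold_profile.tsv")
        anom_res = expression_mod.anom(folds.folds, smap)
        _write_tsv(anom_res.table, out / "anom.tsv")
        manifest.record(
            "profile",
            {"fold_profile": out / "fold_profile.tsv", "anom": out / "anom.tsv"},
            {"anom_h": round(anom_res.h, 9)},
        )

        # --- enrichment -----------------------------------------------------
        esec = cfg.get("enrichment", {})
        if "go_edges" in esec:
            dag = netio.read_go(esec["go_edges"], esec["go_annot"])
            values = folds.folds
        else:
            gocfg = synth.GOGenConfig(
                n_terms=int(esec.get("n_terms", 40)),
                annotation_rate=float(esec.get("annotation_rate", 0.05)),
                n_planted=int(esec.get("n_planted", 1)),
                planted_size=int(esec.get("planted_size", 50)),
                seed=derive_seed(seed, "go"),
            )
            dag, planted = synth.gen_go(gocfg, list(folds.folds.index))
            values = folds.folds
            shift = float(esec.get("planted_shift", 0.0))
            if shift:
                for members in planted.values():
                    values = synth.apply_planted_shift(values, members, shift)
            netio.write_go(dag, out / "go_edges.tsv", out / "go_annot.tsv")
        enr = enrichment_mod.run_enrichment(
            values,
            dag,
            min_size=int(esec.get("min_size", 21)),
            n_samples=int(esec.get("n_samples", 20_000)),
            seed=derive_seed(seed, "enrichment"),
        )
        _write_tsv(enr, out / "enrichment.tsv", index=False)
        manifest.record("enrichment", {"enrichment": out / "enrichment.tsv"},
                        {"n_terms_tested": int(len(enr))})

        manifest.completed = True
    finally:
        (out / "manifest.json").write_text(manifest.to_json())
    return manifest
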