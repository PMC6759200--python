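"""Stage orchestration with run manifests and checksum-based caching.

A run is configured by one YAML document; each stage records its inputs by
sha256 checksum in the manifest, and a rerun skips any stage whose inputs
and outputs are unchanged.  Logs go to stderr; data only to files.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from pathlib import Path
from typing import Any, Callable

import pandas as pd
import yaml

from . import __version__
from .dollo import loss_summary
from .io import (
    read_counts_table,
    read_bed_starts,
    read_newick,
    read_state_matrix,
    write_json,
)
from .mk import mk_from_counts_table, mk_table_frame
from .pairing import best_windows_per_contig, pairing_table
from .sitemodels import lrt_table

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "out_dir": "condevol_out",
    "stages": {
        "losses": {"tree": None, "matrix": None,
                   "assume_ancestral_present": True},
        "mktest": {"counts": None, "tail": "two-sided"},
        "lrt": {"table": None, "df": 2, "family_alpha": 0.05,
                "n_tests": 12, "correct": True},
        "pairing": {"table": None, "confidence": 0.95},
        "probes": {"bed": None, "window_size": 300000, "mode": "sliding"},
    },
}


class ConfigError(ValueError):
    pass


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _log(msg: str) -> None:
    print(f"[condevol] {msg}", file=sys.stderr)


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    merged.update({k: v for k, v in cfg.items() if k != "stages"})
    for stage, opts in (cfg.get("stages") or {}).items():
        if stage not in merged["stages"]:
            raise ConfigError(f"unknown stage {stage!r}")
        merged["stages"][stage].update(opts or {})
    return merged


def _validate(config: dict) -> list[str]:
    """Names of the stages that are actually runnable; errors on bad keys."""
    runnable = []
    stages = config["stages"]
    if stages["losses"]["tree"] or stages["losses"]["matrix"]:
        if not (stages["losses"]["tree"] and stages["losses"]["matrix"]):
            raise ConfigError("stage 'losses' needs both tree and matrix")
        runnable.append("losses")
    for stage, key in (("mktest", "counts"), ("lrt", "table"),
                       ("pairing", "table"), ("probes", "bed")):
        if stages[stage][key]:
            runnable.append(stage)
    return runnable


def _stage_losses(opts: dict, out_dir: Path) -> list[Path]:
    tree = read_newick(opts["tree"])
    matrix = read_state_matrix(opts["matrix"])
    maps, table = loss_summary(tree, matrix,
                               opts.get("assume_ancestral_present", True))
    out_tsv = out_dir / "losses.tsv"
    table.to_csv(out_tsv, sep="\t", index=False)
    write_json({g: m.to_dict() for g, m in maps.items()},
               out_dir / "losses.json")
    return [out_tsv, out_dir / "losses.json"]


def _stage_mktest(opts: dict, out_dir: Path) -> list[Path]:
    df = read_counts_table(opts["counts"])
    results = mk_from_counts_table(df, tail=opts.get("tail", "two-sided"))
    out = out_dir / "mk_results.tsv"
    mk_table_frame(results).to_csv(out, sep="\t", index=False)
    return [out]


def _stage_lrt(opts: dict, out_dir: Path) -> list[Path]:
    df = pd.read_csv(opts["table"], sep="\t")
    out_frame = lrt_table(df, df=opts.get("df", 2),
                          family_alpha=opts.get("family_alpha", 0.05),
                          n_tests=opts.get("n_tests", 12),
                          correct=opts.get("correct", True))
    out = out_dir / "lrt_results.tsv"
    out_frame.to_csv(out, sep="\t", index=False)
    return [out]


def _stage_pairing(opts: dict, out_dir: Path) -> list[Path]:
    df = pd.read_csv(opts["table"], sep="\t")
    rows = [(r.species, str(r.probe), int(r.paired), int(r.total))
            for r in df.itertuples(index=False)]
    _, frame, concordance = pairing_table(
        rows, confidence=opts.get("confidence", 0.95))
    out = out_dir / "pairing_results.tsv"
    frame.to_csv(out, sep="\t", index=False)
    write_json(concordance, out_dir / "pairing_concordance.json")
    return [out, out_dir / "pairing_concordance.json"]


def _stage_probes(opts: dict, out_dir: Path) -> list[Path]:
    starts = read_bed_starts(opts["bed"])
    selections = best_windows_per_contig(
        starts, window_size=opts.get("window_size", 300000),
        mode=opts.get("mode", "sliding"))
    out = out_dir / "probe_windows.bed"
    with out.open("w") as fh:
        for sel in selections:
            fh.write(f"{sel.contig}\t{sel.span[0]}\t{sel.span[1]}\t"
                     f"oligos={sel.oligo_count}\n")
    write_json([vars(s) for s in selections], out_dir / "probe_windows.json")
    return [out, out_dir / "probe_windows.json"]


_STAGE_FUNCS: dict[str, Callable[[dict, Path], list[Path]]] = {
    "losses": _stage_losses,
    "mktest": _stage_mktest,
    "lrt": _stage_lrt,
    "pairing": _stage_pairing,
    "probes": _stage_probes,
}

_STAGE_INPUT_KEYS = {
    "losses": ("tree", "matrix"),
    "mktest": ("counts",),
    "lrt": ("table",),
    "pairing": ("table",),
    "probes": ("bed",),
}


def run_pipeline(config: dict) -> dict:
    """Execute all runnable stages; returns (and writes) the run manifest."""
    runnable = _validate(config)
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = out_dir / "manifest.json"
    previous = (json.loads(manifest_path.read_text())
                if manifest_path.exists() else {"stages": {}})
    manifest: dict[str, Any] = {
        "tool": "condevol",
        "version": __version__,
        "seed": config.get("seed", 0),
        "config": config,
        "stages": {},
    }
    for stage in runnable:
        opts = config["stages"][stage]
        checksums = {
            key: _sha256(Path(opts[key])) for key in _STAGE_INPUT_KEYS[stage]
        }
        prior = previous.get("stages", {}).get(stage)
        if (prior and prior.get("input_checksums") == checksums
                and all(Path(p).exists() for p in prior.get("outputs", []))):
            _log(f"stage {stage}: inputs unchanged, cached")
            manifest["stages"][stage] = {**prior, "cached": True}
            continue
        _log(f"stage {stage}: running")
        t0 = time.perf_counter()
        outputs = _STAGE_FUNCS[stage](opts, out_dir)
        manifest["stages"][stage] = {
            "input_checksums": checksums,
            "outputs": [str(p) for p in outputs],
            "seconds": round(time.perf_counter() - t0, 4),
            "cached": False,
        }
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
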