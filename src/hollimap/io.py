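"""Tabular readers/writers for community mapping datasets and results.

The interchange dialect is TSV with '#'-prefixed header comment lines
(seed, package version, config hash), JSON for models and configs.
Schemas:

  genotypes_{a,b}.tsv : strain_id + one 0/1 column per marker
  pairing.tsv         : pair_id, strain_a, strain_b
  phenotypes.tsv      : long format -- id (pair_id or strain_id),
                        condition (coculture|monoculture), species (E|S),
                        time, abundance
  truth.json          : generating-model record (simulated data only)

All writes are deterministic (fixed column order, fixed float format),
so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataset import CommunityDataset
from .scan import ScanOutput

__all__ = [
    "read_community_dataset",
    "write_community_dataset",
    "write_scan_output",
    "read_scan_tsv",
    "write_effects_tsv",
    "write_power_table",
]


class DataFormatError(ValueError):
    """A file violated the declared schema; message names file and line."""


def _header_lines(seed=None, config_hash=None, extra=()):
    lines = [f"# hollimap {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config_hash is not None:
        lines.append(f"# config_hash: {config_hash}")
    lines.extend(f"# {e}" for e in extra)
    return lines


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _write_tsv(path, df: pd.DataFrame, seed=None, chash=None, index_label=None):
    buf = _io.StringIO()
    for line in _header_lines(seed, chash):
        buf.write(line + "\n")
    df.to_csv(
        buf, sep="\t", index=index_label is not None, index_label=index_label,
        float_format="%.17g", lineterminator="\n",
    )
    Path(path).write_text(buf.getvalue())


def _read_tsv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip", **kw)
    except FileNotFoundError:
        raise FileNotFoundError(f"missing input file: {path}") from None


def write_community_dataset(dataset: CommunityDataset, outdir, seed=None) -> dict:
    """Write a dataset as genotypes_{a,b}.tsv, pairing.tsv, phenotypes.tsv
    and (for simulated data) truth.json; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(dataset.truth) if dataset.truth else None
    paths = {
        "genotypes_a": outdir / "genotypes_a.tsv",
        "genotypes_b": outdir / "genotypes_b.tsv",
        "pairing": outdir / "pairing.tsv",
        "phenotypes": outdir / "phenotypes.tsv",
    }
    _write_tsv(paths["genotypes_a"], dataset.genotypes_a, seed, chash, index_label="strain_id")
    _write_tsv(paths["genotypes_b"], dataset.genotypes_b, seed, chash, index_label="strain_id")
    _write_tsv(paths["pairing"], dataset.pairing, seed, chash)

    rows = []
    t = dataset.times
    for i, rec in dataset.pairing.iterrows():
        for sp, block in (("E", dataset.co_E), ("S", dataset.co_S)):
            for k, tk in enumerate(t):
                rows.append((rec["pair_id"], "coculture", sp, tk, block[i, k]))
    if dataset.mono_E is not None:
        for i, sid in enumerate(dataset.genotypes_a.index):
            for k, tk in enumerate(t):
                rows.append((sid, "monoculture", "E", tk, dataset.mono_E[i, k]))
    if dataset.mono_S is not None:
        for i, sid in enumerate(dataset.genotypes_b.index):
            for k, tk in enumerate(t):
                rows.append((sid, "monoculture", "S", tk, dataset.mono_S[i, k]))
    pheno = pd.DataFrame(rows, columns=["id", "condition", "species", "time", "abundance"])
    _write_tsv(paths["phenotypes"], pheno, seed, chash)

    if dataset.truth is not None:
        paths["truth"] = outdir / "truth.json"
        paths["truth"].write_text(json.dumps(dataset.truth, indent=2, sort_keys=True))
    return paths


def _pivot_block(pheno: pd.DataFrame, ids, condition, species, times, path):
    sub = pheno[(pheno["condition"] == condition) & (pheno["species"] == species)]
    if sub.empty:
        return None
    dup = sub.duplicated(subset=["id", "time"])
    if dup.any():
        row = sub[dup].iloc[0]
        raise DataFormatError(
            f"{path}: duplicated ({row['id']}, {species}, {row['time']}) observation"
        )
    wide = sub.pivot(index="id", columns="time", values="abundance")
    missing = set(ids) - set(wide.index)
    if missing:
        raise DataFormatError(f"{path}: no {condition}/{species} series for {sorted(missing)[:5]}")
    wide = wide.loc[ids]
    if list(wide.columns) != list(times):
        raise DataFormatError(
            f"{path}: {condition}/{species} time grid differs across series"
        )
    return wide.to_numpy(dtype=float)


def read_community_dataset(indir) -> CommunityDataset:
    """Read and cross-validate a dataset directory written by
    :func:`write_community_dataset` (or assembled by hand to the same schema)."""
    indir = Path(indir)
    ga = _read_tsv(indir / "genotypes_a.tsv", index_col="strain_id")
    gb = _read_tsv(indir / "genotypes_b.tsv", index_col="strain_id")
    pairing = _read_tsv(indir / "pairing.tsv")
    for col in ("pair_id", "strain_a", "strain_b"):
        if col not in pairing.columns:
            raise DataFormatError(f"{indir / 'pairing.tsv'}: missing column {col!r}")
    ppath = indir / "phenotypes.tsv"
    pheno = _read_tsv(ppath)
    required = {"id", "condition", "species", "time", "abundance"}
    if not required.issubset(pheno.columns):
        raise DataFormatError(
            f"{ppath}: missing columns {sorted(required - set(pheno.columns))}"
        )
    if not np.issubdtype(pheno["abundance"].dtype, np.number):
        bad = pheno[pd.to_numeric(pheno["abundance"], errors="coerce").isna()]
        line = bad.index[0] + 2 if len(bad) else "?"
        raise DataFormatError(f"{ppath}: non-numeric abundance near line {line}")

    co = pheno[pheno["condition"] == "coculture"]
    unknown_pairs = set(co["id"]) - set(pairing["pair_id"])
    if unknown_pairs:
        raise DataFormatError(
            f"{ppath}: phenotype rows reference unknown pair ids {sorted(unknown_pairs)[:5]}"
        )
    times = np.array(sorted(co["time"].unique()), dtype=float)
    co_E = _pivot_block(pheno, list(pairing["pair_id"]), "coculture", "E", times, ppath)
    co_S = _pivot_block(pheno, list(pairing["pair_id"]), "coculture", "S", times, ppath)
    if co_E is None or co_S is None:
        raise DataFormatError(f"{ppath}: co-culture series for both species are required")
    mono_E = _pivot_block(pheno, list(ga.index), "monoculture", "E", times, ppath)
    mono_S = _pivot_block(pheno, list(gb.index), "monoculture", "S", times, ppath)

    truth = None
    tpath = indir / "truth.json"
    if tpath.exists():
        truth = json.loads(tpath.read_text())
    return CommunityDataset(
        genotypes_a=ga,
        genotypes_b=gb,
        pairing=pairing,
        times=times,
        co_E=co_E,
        co_S=co_S,
        mono_E=mono_E,
        mono_S=mono_S,
        truth=truth,
    )


def scan_output_frame(output: ScanOutput) -> pd.DataFrame:
    """Flatten scan results: one row per tested unit, theta estimates inline."""
    rows = []
    for res in output.results:
        row = {}
        if len(res.marker) == 2:
            row["marker_a"], row["marker_b"] = res.marker
        else:
            row["marker"] = res.marker[0]
        row.update(
            lr=res.lr,
            threshold=res.threshold,
            significant=res.significant,
            test_type=res.test_type,
            loglik_null=res.loglik_null,
            loglik_alt=res.loglik_alt,
        )
        for lab in sorted(res.thetas):
            for fname, val in zip(
                ("r_e", "K_e", "alpha_es", "r_s", "K_s", "alpha_se"),
                res.thetas[lab].as_array(),
            ):
                row[f"{lab}_{fname}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def write_scan_output(output: ScanOutput, path, seed=None, chash=None) -> None:
    """Scan TSV plus a .skipped.log sidecar naming excluded units."""
    path = Path(path)
    _write_tsv(path, scan_output_frame(output), seed, chash)
    side = path.with_suffix(path.suffix + ".skipped.log")
    lines = [f"{'_x_'.join(map(str, m)) if isinstance(m, tuple) else m}\t{reason}"
             for m, reason in output.skipped]
    side.write_text("\n".join(lines) + ("\n" if lines else ""))


def read_scan_tsv(path) -> pd.DataFrame:
    return _read_tsv(path)


def write_effects_tsv(path, decompositions: dict, variances: dict, seed=None) -> None:
    """Effect curves per species: time, species, mean, direct, indirect,
    epistatic, var_direct, var_indirect, var_epistatic."""
    rows = []
    for sp, dec in decompositions.items():
        var = variances[sp]
        for k, t in enumerate(dec.times):
            rows.append(
                (
                    t, sp, dec.mean[k], dec.direct[k], dec.indirect[k], dec.epistatic[k],
                    var["direct"][k], var["indirect"][k], var["epistatic"][k],
                )
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "time", "species", "mean", "direct", "indirect", "epistatic",
            "var_direct", "var_indirect", "var_epistatic",
        ],
    )
    _write_tsv(path, df, seed)


def write_power_table(path, table: pd.DataFrame, seed=None, chash=None) -> None:
    _write_tsv(path, table, seed, chash)
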