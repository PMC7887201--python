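"""Readers and writers for the plain-text data formats, plus YAML config.

All formats are tab-separated text with a leading ``# format: 1`` comment:

* genotype file — header ``locus  chrom1  chrom2``, one row per locus,
  1-based contiguous locus indices, 0/1 allele desirability;
* targets file — one 1-based locus index per line (``#`` comments allowed);
* recombination map — header ``interval  r``; row ``i`` is the frequency
  between loci ``i`` and ``i + 1`` (1-based, contiguous).

The 1-based-on-disk / 0-based-in-memory conversion happens here and nowhere
else.
"""

from __future__ import annotations

from pathlib import Path
from typing import Tuple

import numpy as np
import pandas as pd
import yaml

from .genetics import Genotype, RecombMap, TargetSet
from .lookahead import LookaheadConfig
from .pipeline import SCENARIO_CROSSES, ProgramConfig

__all__ = [
    "read_genotype",
    "write_genotype",
    "read_targets",
    "write_targets",
    "read_recomb_map",
    "write_recomb_map",
    "load_config",
]

FORMAT_LINE = "# format: 1"


def _read_table(path, columns) -> Tuple[pd.DataFrame, int]:
    """Read a headered TSV, returning the frame and the file line number of
    the first data row (for error messages)."""
    path = Path(path)
    n_comment = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n_comment += 1
            else:
                break
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.ParserError as err:
        raise ValueError(f"{path}: not a parseable TSV ({err})") from err
    if list(df.columns) != list(columns):
        raise ValueError(
            f"{path}: expected columns {list(columns)}, found {list(df.columns)}"
        )
    return df, n_comment + 2


def _require_int(df: pd.DataFrame, col: str, path, first_line: int) -> np.ndarray:
    values = pd.to_numeric(df[col], errors="coerce")
    bad = values.isna() | (values != values.round())
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"{path}: line {first_line + row}: non-integer value "
            f"{df[col].iloc[row]!r} in column {col!r}"
        )
    return values.to_numpy(dtype=np.int64)


def read_genotype(path) -> Genotype:
    """Parse a genotype TSV (``locus  chrom1  chrom2``) into a :class:`Genotype`."""
    df, first_line = _read_table(path, ("locus", "chrom1", "chrom2"))
    loci = _require_int(df, "locus", path, first_line)
    L = len(df)
    expected = np.arange(1, L + 1)
    if not np.array_equal(loci, expected):
        row = int(np.flatnonzero(loci != expected)[0]) if L else 0
        raise ValueError(
            f"{path}: line {first_line + row}: loci must be contiguous 1..L; "
            f"expected locus {expected[row] if L else 1}, found {loci[row] if L else 'nothing'}"
        )
    cols = []
    for col in ("chrom1", "chrom2"):
        vals = _require_int(df, col, path, first_line)
        bad = ~np.isin(vals, (0, 1))
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: line {first_line + row}: allele value must be 0 or 1, "
                f"found {vals[row]} in column {col!r}"
            )
        cols.append(vals)
    return Genotype.from_haplotypes(cols[0], cols[1])


def write_genotype(genotype: Genotype, path) -> None:
    with open(path, "w") as fh:
        fh.write(FORMAT_LINE + "\n")
        fh.write("locus\tchrom1\tchrom2\n")
        for l in range(genotype.L):
            fh.write(f"{l + 1}\t{genotype.alleles[l, 0]}\t{genotype.alleles[l, 1]}\n")


def read_targets(path) -> TargetSet:
    """One 1-based locus index per line."""
    values = np.atleast_1d(np.loadtxt(path, dtype=np.int64, comments="#", ndmin=1))
    if (values < 1).any():
        raise ValueError(f"{path}: target locus indices are 1-based and must be >= 1")
    return TargetSet.from_one_based(values)


def write_targets(targets: TargetSet, path) -> None:
    with open(path, "w") as fh:
        fh.write(FORMAT_LINE + "\n")
        for locus in targets.to_one_based():
            fh.write(f"{locus}\n")


def read_recomb_map(path) -> RecombMap:
    """Parse a recombination-map TSV (``interval  r``)."""
    df, first_line = _read_table(path, ("interval", "r"))
    intervals = _require_int(df, "interval", path, first_line)
    n = len(df)
    expected = np.arange(1, n + 1)
    if not np.array_equal(intervals, expected):
        row = int(np.flatnonzero(intervals != expected)[0]) if n else 0
        raise ValueError(
            f"{path}: line {first_line + row}: intervals must be contiguous 1..L-1"
        )
    r = pd.to_numeric(df["r"], errors="coerce").to_numpy(dtype=np.float64)
    if np.isnan(r).any():
        row = int(np.flatnonzero(np.isnan(r))[0])
        raise ValueError(
            f"{path}: line {first_line + row}: non-numeric recombination frequency"
        )
    if (r < 0).any() or (r > 0.5).any():
        row = int(np.flatnonzero((r < 0) | (r > 0.5))[0])
        raise ValueError(
            f"{path}: line {first_line + row}: frequencies must lie in [0, 0.5]"
        )
    return RecombMap(r)


def write_recomb_map(recomb: RecombMap, path) -> None:
    with open(path, "w") as fh:
        fh.write(FORMAT_LINE + "\n")
        fh.write("interval\tr\n")
        for i, value in enumerate(recomb.r, start=1):
            fh.write(f"{i}\t{value:.10g}\n")


_TOP_KEYS = {
    "scenario",
    "T",
    "crosses_per_generation",
    "progeny_per_cross",
    "method",
    "replicates",
    "threshold",
    "seed",
    "lmc",
}
_LMC_KEYS = {"P", "K", "threshold", "attempt_cap"}


def load_config(path) -> ProgramConfig:
    """Load a YAML program configuration with validation and defaults.

    Recognised keys: ``scenario`` (1 or 2, presets for crosses per
    generation), ``T`` (backcross generations), ``crosses_per_generation``,
    ``progeny_per_cross``, ``method``, ``replicates``, ``threshold``,
    ``seed`` and the ``lmc`` block ``{P, K, threshold, attempt_cap}``.
    Unknown keys are rejected; an empty file yields all defaults
    (scenario 1 resources).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw = {} if raw is None else raw
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    problems = []
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        problems.append(f"unknown keys: {sorted(unknown)}")
    lmc_raw = raw.get("lmc") or {}
    if not isinstance(lmc_raw, dict):
        problems.append("lmc must be a mapping")
        lmc_raw = {}
    unknown_lmc = set(lmc_raw) - _LMC_KEYS
    if unknown_lmc:
        problems.append(f"unknown lmc keys: {sorted(unknown_lmc)}")
    if "scenario" in raw and "crosses_per_generation" in raw:
        problems.append("give either scenario or crosses_per_generation, not both")
    if problems:
        raise ValueError(f"{path}: invalid configuration: " + "; ".join(problems))

    crosses = raw.get("crosses_per_generation")
    if "scenario" in raw:
        if raw["scenario"] not in SCENARIO_CROSSES:
            raise ValueError(
                f"{path}: scenario must be one of {sorted(SCENARIO_CROSSES)}"
            )
        crosses = SCENARIO_CROSSES[raw["scenario"]]
    kwargs = dict(
        n_backcross=raw.get("T", 3),
        crosses_per_generation=crosses if crosses is not None else SCENARIO_CROSSES[1],
        progeny_per_cross=raw.get("progeny_per_cross", 200),
        method=raw.get("method", "gebv"),
        replicates=raw.get("replicates", 100),
        success_threshold=raw.get("threshold", 95.0),
        seed=raw.get("seed", 0),
    )
    lookahead_kwargs = {}
    if "P" in lmc_raw:
        lookahead_kwargs["rounds"] = lmc_raw["P"]
    if "K" in lmc_raw:
        lookahead_kwargs["selfing_progeny"] = lmc_raw["K"]
    if "threshold" in lmc_raw:
        lookahead_kwargs["success_threshold"] = lmc_raw["threshold"]
    if "attempt_cap" in lmc_raw:
        lookahead_kwargs["attempt_cap"] = lmc_raw["attempt_cap"]
    try:
        lookahead = LookaheadConfig(
            target_generation=kwargs["n_backcross"],
            **{
                {"attempt_cap": "max_gamete_attempts"}.get(k, k): v
                for k, v in lookahead_kwargs.items()
            },
        )
        return ProgramConfig(lookahead=lookahead, **kwargs)
    except (ValueError, TypeError) as err:
        raise ValueError(f"{path}: invalid configuration: {err}") from err
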