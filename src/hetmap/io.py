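"""File formats, configuration and result serialization.

Phenotypes travel as long-format CSV (``sample_id,time,x1,x2``, one row per
individual per observation time), markers as a two-column TSV
(``sample_id<TAB>genotype`` with genotype in MM/Mm/mm or 2/1/0) or,
optionally, a single-site VCF whose diploid GT field is mapped
0/0 -> MM, 0/1 or 1/0 -> Mm, 1/1 -> mm.  Run configuration is a JSON
document validated against a strict schema (unknown keys rejected).
Results serialize to JSON with a schema version and the full provenance
(config and seeds); floats round-trip bitwise through ``json``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import covariance as cov
from . import dynamics as dyn
from . import genetics as gen
from . import likelihood as lik
from .errors import (
    DataFormatError,
    DuplicateCellError,
    MissingCellError,
    SampleMismatchError,
    UnknownGenotypeCodeError,
)

logger = logging.getLogger("hetmap")

SCHEMA_VERSION = "1.0"
TOOL_VERSION = "0.1.0"

_MARKER_CODES = {"MM": 2, "Mm": 1, "mm": 0, "2": 2, "1": 1, "0": 0}


# ---------------------------------------------------------------------------
# configuration

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelSection(_Strict):
    name: str = Field(default="linear", pattern="^(linear|nonlinear)$")
    w_convention: str = Field(default="proportion", pattern="^(proportion|size)$")


class TimeSection(_Strict):
    t0: float = 0.0
    points: list[float] = Field(default_factory=lambda: [float(t) for t in range(1, 10)])
    h: float = 0.05


class InitSection(_Strict):
    x1: float = 1.0
    x2: float = 1.0


class FitSection(_Strict):
    max_em_iter: int = 500
    em_tol: float = 1e-6
    n_starts: int = 5
    inner_maxiter: int = 80
    seed: int = 0


class PermSection(_Strict):
    n_perm: int = 100
    alpha: float = 0.05
    seed: int = 0


class RunConfig(_Strict):
    """Validated run configuration (strict: unknown keys rejected)."""

    model: ModelSection = Field(default_factory=ModelSection)
    time: TimeSection = Field(default_factory=TimeSection)
    init: InitSection = Field(default_factory=InitSection)
    fit: FitSection = Field(default_factory=FitSection)
    perm: PermSection = Field(default_factory=PermSection)

    def grid(self) -> dyn.TimeGrid:
        return dyn.TimeGrid(
            t0=self.time.t0, times=tuple(self.time.points), h=self.time.h
        )

    def init_state(self) -> dyn.State:
        return dyn.State(self.init.x1, self.init.x2)

    def fit_config(self):
        from . import estimation as est

        return est.FitConfig(
            max_em_iter=self.fit.max_em_iter,
            em_tol=self.fit.em_tol,
            n_starts=self.fit.n_starts,
            inner_maxiter=self.fit.inner_maxiter,
            seed=self.fit.seed,
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))


# ---------------------------------------------------------------------------
# dataset reading / writing

def read_markers(path) -> pd.Series:
    """Marker TSV -> Series of integer codes indexed by sample_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["sample_id", "genotype"]:
        raise DataFormatError(
            f"marker file must have columns sample_id, genotype; got "
            f"{list(df.columns)}"
        )
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise DuplicateCellError(f"duplicate marker record for sample {dup!r}")
    bad = ~df["genotype"].isin(_MARKER_CODES)
    if bad.any():
        code = df.loc[bad, "genotype"].iloc[0]
        raise UnknownGenotypeCodeError(
            f"unknown marker genotype code {code!r} (expected MM/Mm/mm or 2/1/0)"
        )
    return pd.Series(
        [_MARKER_CODES[g] for g in df["genotype"]],
        index=df["sample_id"].tolist(),
    )


def read_markers_vcf(path) -> pd.Series:
    """Single-site VCF -> marker codes (requires pysam; diploid GT only)."""
    try:
        import pysam
    except ImportError as exc:  # pragma: no cover
        raise DataFormatError("reading VCF markers requires pysam") from exc
    with pysam.VariantFile(str(path)) as vf:
        records = list(vf)
        if len(records) != 1:
            raise DataFormatError(
                f"marker VCF must contain exactly one site, found {len(records)}"
            )
        rec = records[0]
        if rec.alts is not None and len(rec.alts) > 1:
            raise DataFormatError("multi-allelic marker sites are not supported")
        codes, samples = [], []
        for name, sample in rec.samples.items():
            gt = sample.get("GT")
            if gt is None or len(gt) != 2 or None in gt:
                raise UnknownGenotypeCodeError(
                    f"sample {name!r} has no diploid GT call"
                )
            codes.append(2 - int(gt[0]) - int(gt[1]))  # number of ref alleles
            samples.append(name)
    return pd.Series(codes, index=samples)


def read_dataset(pheno_path, marker_path, config: RunConfig) -> lik.Dataset:
    """Assemble a Dataset from a phenotype CSV and a marker TSV/VCF.

    Validates grid completeness and sample consistency; distinct named
    errors identify missing cells, duplicates, sample mismatches and
    unknown genotype codes.
    """
    grid = config.grid()
    df = pd.read_csv(pheno_path)
    expected_cols = ["sample_id", "time", "x1", "x2"]
    if list(df.columns) != expected_cols:
        raise DataFormatError(
            f"phenotype file must have columns {expected_cols}, got "
            f"{list(df.columns)}"
        )
    if str(marker_path).endswith(".vcf") or str(marker_path).endswith(".vcf.gz"):
        markers = read_markers_vcf(marker_path)
    else:
        markers = read_markers(marker_path)
    dups = df.duplicated(subset=["sample_id", "time"])
    if dups.any():
        row = df.loc[dups].iloc[0]
        raise DuplicateCellError(
            f"duplicate phenotype row for sample {row['sample_id']!r} at "
            f"time {row['time']}"
        )
    pheno_samples = list(dict.fromkeys(df["sample_id"]))
    if set(pheno_samples) != set(markers.index):
        only_p = sorted(set(pheno_samples) - set(markers.index))
        only_m = sorted(set(markers.index) - set(pheno_samples))
        raise SampleMismatchError(
            f"sample sets differ (phenotypes only: {only_p[:3]}, "
            f"markers only: {only_m[:3]})"
        )
    piv = df.set_index(["sample_id", "time"])
    times = list(grid.times)
    Y = np.empty((len(pheno_samples), 2 * grid.T))
    for i, sid in enumerate(pheno_samples):
        for k, t in enumerate(times):
            try:
                row = piv.loc[(sid, t)]
            except KeyError:
                raise MissingCellError(
                    f"missing phenotype row for sample {sid!r} at time {t}"
                ) from None
            Y[i, k] = row["x1"]
            Y[i, grid.T + k] = row["x2"]
    marker = markers.loc[pheno_samples].to_numpy()
    data = lik.Dataset(marker=marker, Y=Y, grid=grid, sample_ids=pheno_samples)
    counts = {m: int((marker == c).sum()) for m, c in (("MM", 2), ("Mm", 1), ("mm", 0))}
    logger.info(
        "read dataset: n=%d, T=%d, marker counts %s", data.n, grid.T, counts
    )
    return data


def write_dataset(
    data: lik.Dataset, pheno_path, marker_path, truth_path=None
) -> None:
    """Write a Dataset to the long-format CSV + marker TSV (and optional
    truth TSV)."""
    ids = data.sample_ids or [f"S{i:04d}" for i in range(data.n)]
    T = data.grid.T
    rows = []
    for i, sid in enumerate(ids):
        for k, t in enumerate(data.grid.times):
            rows.append((sid, t, data.Y[i, k], data.Y[i, T + k]))
    pd.DataFrame(rows, columns=["sample_id", "time", "x1", "x2"]).to_csv(
        pheno_path, index=False
    )
    code_names = {2: "MM", 1: "Mm", 0: "mm"}
    pd.DataFrame(
        {"sample_id": ids, "genotype": [code_names[int(m)] for m in data.marker]}
    ).to_csv(marker_path, sep="\t", index=False)
    if truth_path is not None and data.truth_qtl is not None:
        pd.DataFrame(
            {
                "sample_id": ids,
                "qtl_genotype": [
                    gen.QTL_GENOTYPES[int(j)] for j in data.truth_qtl
                ],
                "qtl_index": [int(j) for j in data.truth_qtl],
            }
        ).to_csv(truth_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# result serialization

def _to_jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (gen.HaplotypeFreqs, gen.GeneticParams, cov.SADParams,
                        dyn.State, dyn.TimeGrid)):
        return {
            k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()
        }
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _to_jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def write_results(result, path, config: RunConfig | None = None) -> None:
    """Serialize a result object (fit, test, or replicate summary) to JSON
    with schema version and provenance; floats round-trip bitwise."""
    doc = {
        "schema_version": SCHEMA_VERSION,
        "tool_version": TOOL_VERSION,
        "result_type": type(result).__name__,
        "result": _to_jsonable(result),
    }
    if config is not None:
        doc["config"] = config.model_dump()
    # key order is preserved so tabulated results keep the conventional
    # parameter row order
    Path(path).write_text(json.dumps(doc, indent=2))


def read_results(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
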