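"""Declarative YAML-driven pipeline execution.

A workflow file names input datasets and an ordered list of steps, each
dispatching one registered operation with validated parameters::

    version: 1
    seed: 42
    datasets:
      nir: phantom/nir.h5
      mir: phantom/mir.h5
    steps:
      - op: correct_vignette
        inputs: [mir]
        params: {sigma: 10, epsilon: 5}
      - op: align_ecc
        inputs: [nir]
        params: {reference: mir}

Validation is all-or-nothing: no step executes unless every step passes
preflight (known op, required params present, inputs resolvable).  Every
executed step appends to a provenance log (op, params, content hashes of
inputs and outputs, wall time); identical spec + inputs + seed reproduce
identical output hashes.  Results land in a local output directory as
cube containers plus ``provenance.json`` and ``metrics.json`` — the
local-filesystem storage contract standing in for a remote repository.
If the output directory already holds registered cubes of distinct
modalities for the same sample, :func:`auto_merge` fuses them.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import yaml

from .analysis import ClusterResult, minibatch_kmeans, silhouette_mean
from .datacube import DataCube, read_cube, write_cube
from .errors import ConfigError
from .fusion import fuse_cubes
from .preprocess import (
    ReferenceSpectrum,
    SpikeParams,
    VignetteParams,
    correct_vignette,
    load_reference_csv,
    minmax_normalize,
    reference_correct,
    remove_background,
    remove_spikes,
    spa_select_bands,
)
from .registration import align_ecc, register_layers_keypoint, resize_cube


@dataclass(frozen=True)
class OpSpec:
    """Registry entry: callable plus its parameter contract."""

    run: Callable[..., Any]
    required: tuple[str, ...] = ()
    optional: tuple[str, ...] = ()
    n_inputs: int | None = 1  # None = variadic (>= 2)


@dataclass
class WorkflowStep:
    op: str
    inputs: list[str]
    output: str
    params: dict[str, Any] = field(default_factory=dict)


@dataclass
class WorkflowSpec:
    version: int
    seed: int
    datasets: dict[str, str]
    steps: list[WorkflowStep]
    settings: dict[str, Any] = field(default_factory=dict)


# -- operation adapters ---------------------------------------------------

def _op_reference_correct(cubes, params, ctx):
    ref = ReferenceSpectrum(np.asarray(params["reference"], dtype=float)) \
        if "reference" in params else load_reference_csv(params["reference_csv"])
    return reference_correct(cubes[0], ref)


def _op_remove_spikes(cubes, params, ctx):
    return remove_spikes(cubes[0], SpikeParams(
        threshold=params.get("threshold", SpikeParams().threshold),
        window=params.get("window", SpikeParams().window)))


def _op_correct_vignette(cubes, params, ctx):
    return correct_vignette(cubes[0], VignetteParams(
        sigma=params["sigma"],
        epsilon=params.get("epsilon", VignetteParams(sigma=1).epsilon)))


def _op_remove_background(cubes, params, ctx):
    return remove_background(cubes[0])


def _op_minmax(cubes, params, ctx):
    return minmax_normalize(cubes[0], per=params.get("per", "spectrum"))


def _op_spa(cubes, params, ctx):
    cube, _ = spa_select_bands(cubes[0], int(params["k"]))
    return cube


def _op_resize(cubes, params, ctx):
    if "match" in params:
        target = ctx["datasets"][params["match"]].data.shape[:2]
    else:
        target = (int(params["rows"]), int(params["cols"]))
    return resize_cube(cubes[0], target)


def _op_layers(cubes, params, ctx):
    cube, _ = register_layers_keypoint(
        cubes[0], reference_band=int(params.get("reference_band", 0)),
        fallback_identity=bool(params.get("fallback_identity", False)),
        seed=ctx["seed"])
    return cube


def _op_ecc(cubes, params, ctx):
    reference = ctx["datasets"][params["reference"]]
    cube, t = align_ecc(
        cubes[0], reference,
        model=params.get("model", "euclidean"),
        max_iter=int(params.get("max_iter", 200)),
        eps=float(params.get("eps", 1e-6)))
    ctx["transforms"][ctx["step_output"]] = t
    return cube


def _op_fuse(cubes, params, ctx):
    return fuse_cubes(list(cubes), normalize=params.get("normalize", "band"))


def _op_kmeans(cubes, params, ctx):
    result = minibatch_kmeans(
        cubes[0],
        k=int(params.get("k", 9)),
        seed=ctx["seed"],
        batch_size=int(params.get("batch_size", 1024)),
        max_batches=int(params.get("max_batches", 300)))
    fg = cubes[0].foreground()
    if params.get("silhouette", True):
        ctx["metrics"]["silhouette_mean"] = silhouette_mean(
            cubes[0].data[fg].astype(np.float64), result.labels[fg],
            seed=ctx["seed"])
    ctx["metrics"]["inertia"] = result.inertia
    return result


OP_REGISTRY: dict[str, OpSpec] = {
    "reference_correct": OpSpec(_op_reference_correct,
                                optional=("reference", "reference_csv")),
    "remove_spikes": OpSpec(_op_remove_spikes, optional=("threshold", "window")),
    "correct_vignette": OpSpec(_op_correct_vignette, required=("sigma",),
                               optional=("epsilon",)),
    "remove_background": OpSpec(_op_remove_background),
    "minmax_normalize": OpSpec(_op_minmax, optional=("per",)),
    "spa_select_bands": OpSpec(_op_spa, required=("k",)),
    "resize_cube": OpSpec(_op_resize, optional=("rows", "cols", "match")),
    "register_layers_keypoint": OpSpec(
        _op_layers, optional=("reference_band", "fallback_identity")),
    "align_ecc": OpSpec(_op_ecc, required=("reference",),
                        optional=("model", "max_iter", "eps")),
    "fuse_cubes": OpSpec(_op_fuse, optional=("normalize",), n_inputs=None),
    "minibatch_kmeans": OpSpec(
        _op_kmeans, optional=("k", "batch_size", "max_batches", "silhouette")),
}


def parse_workflow(yaml_text: str) -> WorkflowSpec:
    """Parse and fully validate a workflow definition before execution."""
    try:
        doc = yaml.safe_load(yaml_text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"invalid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError("workflow document must be a mapping")
    datasets = doc.get("datasets", {}) or {}
    if not isinstance(datasets, dict):
        raise ConfigError("'datasets' must map names to paths")
    steps_raw = doc.get("steps", []) or []
    known = set(datasets)
    steps: list[WorkflowStep] = []
    for i, raw in enumerate(steps_raw):
        if not isinstance(raw, dict) or "op" not in raw:
            raise ConfigError(f"step {i}: missing 'op'")
        op = raw["op"]
        if op not in OP_REGISTRY:
            raise ConfigError(f"step {i}: unknown op {op!r}")
        spec = OP_REGISTRY[op]
        inputs = raw.get("inputs", [])
        if isinstance(inputs, str):
            inputs = [inputs]
        if spec.n_inputs is None:
            if len(inputs) < 2:
                raise ConfigError(f"step {i} ({op}): needs >= 2 inputs")
        elif len(inputs) != spec.n_inputs:
            raise ConfigError(
                f"step {i} ({op}): expected {spec.n_inputs} input(s), "
                f"got {len(inputs)}")
        params = raw.get("params", {}) or {}
        allowed = set(spec.required) | set(spec.optional)
        for key in params:
            if key not in allowed:
                raise ConfigError(f"step {i} ({op}): unknown param {key!r}")
        for key in spec.required:
            if key not in params:
                raise ConfigError(f"step {i} ({op}): missing required param {key!r}")
        if op == "reference_correct" and not (
                "reference" in params or "reference_csv" in params):
            raise ConfigError(
                f"step {i} (reference_correct): missing required param "
                "'reference_csv' (or inline 'reference')")
        referenced = list(inputs)
        if op in ("align_ecc",):
            referenced.append(params["reference"])
        if op == "resize_cube" and "match" in params:
            referenced.append(params["match"])
        for name in referenced:
            if name not in known:
                raise ConfigError(
                    f"step {i} ({op}): unknown dataset {name!r}")
        output = raw.get("output", inputs[0])
        known.add(output)
        steps.append(WorkflowStep(op=op, inputs=list(inputs), output=output,
                                  params=dict(params)))
    return WorkflowSpec(
        version=int(doc.get("version", 1)),
        seed=int(doc.get("seed", 0)),
        datasets={str(k): str(v) for k, v in datasets.items()},
        steps=steps,
        settings=dict(doc.get("settings", {}) or {}),
    )


def _content_hash(obj: Any) -> str:
    h = hashlib.sha256()
    if isinstance(obj, DataCube):
        h.update(np.ascontiguousarray(obj.data, dtype=np.float32).tobytes())
        h.update(np.ascontiguousarray(obj.wavelengths.values).tobytes())
        if obj.mask is not None:
            h.update(np.packbits(obj.mask).tobytes())
        h.update(obj.modality.value.encode())
    elif isinstance(obj, ClusterResult):
        h.update(obj.labels.tobytes())
        h.update(np.ascontiguousarray(obj.centers).tobytes())
        h.update(np.float64(obj.inertia).tobytes())
    else:
        h.update(json.dumps(obj, sort_keys=True, default=str).encode())
    return h.hexdigest()


def run_workflow(spec: WorkflowSpec, inputs: dict[str, str | DataCube],
                 out_dir: str) -> dict[str, Any]:
    """Execute a validated workflow and write its artifacts.

    ``inputs`` maps dataset names to cube container paths (or in-memory
    cubes).  Returns the run report; raises on step failure after writing
    the completed-step manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    datasets: dict[str, Any] = {}
    for name, src in {**spec.datasets, **inputs}.items():
        datasets[name] = src if isinstance(src, DataCube) else read_cube(str(src))

    ctx: dict[str, Any] = {"seed": spec.seed, "datasets": datasets,
                           "metrics": {}, "transforms": {},
                           "out_dir": str(out)}
    provenance: list[dict[str, Any]] = []
    report = {"seed": spec.seed, "steps_run": 0, "failed_step": None,
              "outputs": {}, "metrics": ctx["metrics"]}
    try:
        for i, step in enumerate(spec.steps):
            t0 = time.perf_counter()
            in_hashes = {n: _content_hash(datasets[n]) for n in step.inputs}
            ctx["step_output"] = step.output
            result = OP_REGISTRY[step.op].run(
                [datasets[n] for n in step.inputs], step.params, ctx)
            datasets[step.output] = result
            provenance.append({
                "step": i, "op": step.op, "params": step.params,
                "inputs": in_hashes,
                "outputs": {step.output: _content_hash(result)},
                "wall_time_s": round(time.perf_counter() - t0, 4),
            })
            report["steps_run"] += 1
    except Exception as exc:
        report["failed_step"] = {"index": report["steps_run"],
                                 "op": spec.steps[report["steps_run"]].op,
                                 "error": str(exc)}
        _write_manifest(out, spec, provenance, report, datasets)
        raise
    _write_manifest(out, spec, provenance, report, datasets)
    if spec.settings.get("auto_merge"):
        merged = auto_merge(str(out))
        if merged is not None:
            report["outputs"]["fused_auto"] = merged
    return report


def _write_manifest(out: Path, spec: WorkflowSpec, provenance, report,
                    datasets) -> None:
    for name, obj in datasets.items():
        if isinstance(obj, DataCube):
            path = out / f"{name}.h5"
            write_cube(obj, str(path))
            report["outputs"][name] = str(path)
        elif isinstance(obj, ClusterResult):
            np.savetxt(out / f"{name}_centers.csv", obj.centers, delimiter=",")
            _write_label_map(obj, out / f"{name}_labels.h5")
            report["outputs"][name] = str(out / f"{name}_labels.h5")
    (out / "provenance.json").write_text(json.dumps({
        "seed": spec.seed,
        "steps": provenance,
        "failed_step": report["failed_step"],
        "settings": spec.settings,
    }, indent=2))
    (out / "metrics.json").write_text(json.dumps(report["metrics"], indent=2))


def _write_label_map(result: ClusterResult, path: Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("labels", data=result.labels.astype(np.int32))
        f.attrs["k"] = result.k
        f.attrs["seed"] = result.seed
        f.attrs["inertia"] = result.inertia


def read_label_map(path: str) -> ClusterResult:
    import h5py

    with h5py.File(path, "r") as f:
        labels = np.asarray(f["labels"], dtype=np.int32)
        k = int(f.attrs["k"])
        fg = labels >= 0
        centers = np.zeros((k, 1))
        return ClusterResult(labels=labels, centers=centers,
                             inertia=float(f.attrs["inertia"]), k=k,
                             seed=int(f.attrs["seed"]))


def auto_merge(out_dir: str) -> str | None:
    """Fuse registered single-modality cubes already present in ``out_dir``.

    Scans for cube containers of distinct non-FUSED modalities sharing one
    spatial grid; when at least two are present, writes ``fused_auto.h5``
    and returns its path (the local analogue of a repository-triggered
    merge).  Returns None when nothing can be merged.
    """
    out = Path(out_dir)
    candidates: dict[str, DataCube] = {}
    for path in sorted(out.glob("*.h5")):
        if path.name.endswith("_labels.h5") or path.name == "fused_auto.h5":
            continue
        try:
            cube = read_cube(str(path))
        except Exception:
            continue
        if cube.modality.value == "FUSED":
            continue
        candidates.setdefault(cube.modality.value, cube)
    if len(candidates) < 2:
        return None
    order = [m for m in ("NIR", "MIR", "RGB") if m in candidates]
    # sharing one pixel grid is the precondition for (and proxy of)
    # completed registration
    shapes = {candidates[m].data.shape[:2] for m in order}
    if len(shapes) != 1:
        return None
    fused = fuse_cubes([candidates[m] for m in order])
    path = out / "fused_auto.h5"
    write_cube(fused, str(path))
    return str(path)
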