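"""Strict file formats: response CSV, fit-result JSON, density TSV."""

from __future__ import annotations

import json

import numpy as np

from .grid_spline import RamsayDensity, build_basis, build_grid, ramsay_pdf
from .irt_core import ItemSet, ResponseMatrix
from .saem_engine import FitResult

__all__ = ["read_responses", "write_responses", "write_fit", "read_fit"]


def read_responses(path) -> ResponseMatrix:
    """Parse a response CSV: header row of item identifiers, then one row of
    0/1 cells per examinee.  Any other token is an error naming its cell."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ValueError(f"{path}: empty file")
        item_ids = [h.strip() for h in header.split(",")]
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            cells = line.split(",")
            if len(cells) != len(item_ids):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(item_ids)} cells, "
                    f"got {len(cells)}")
            row = []
            for col, cell in enumerate(cells, start=1):
                cell = cell.strip()
                if cell not in ("0", "1"):
                    raise ValueError(
                        f"{path}:{lineno}: column {col}: invalid response "
                        f"{cell!r} (must be 0 or 1)")
                row.append(int(cell))
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no response rows")
    return ResponseMatrix(np.array(rows, dtype=np.int8), item_ids=item_ids)


def write_responses(U: ResponseMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(",".join(U.item_ids) + "\n")
        for row in U.u:
            fh.write(",".join(str(int(v)) for v in row) + "\n")


def write_fit(result: FitResult, path, knots: int | None = None,
              degree: int | None = None) -> None:
    """JSON-serialize a FitResult (lossless round trip via read_fit)."""
    density = result.density
    if isinstance(density, RamsayDensity):
        g = density.g
        grid = density.grid
        spec = {"knots": density.basis.spec.knots,
                "degree": density.basis.spec.degree}
    else:
        g = np.asarray(density)
        grid = build_grid()
        spec = {"knots": knots, "degree": degree}
    payload = {
        "items": {"a": result.items.a.tolist(), "b": result.items.b.tolist(),
                  "c": result.items.c.tolist()},
        "eta": None if result.eta is None else np.asarray(result.eta).tolist(),
        "density": {"theta": grid.points.tolist(), "mass": g.tolist(),
                    "lo": grid.lo, "hi": grid.hi, "step": grid.step},
        "spline": spec,
        "converged": bool(result.converged),
        "iterations": int(result.iterations),
        "marginal_loglik": float(result.marginal_loglik),
        "n_params": int(result.n_params),
        "criteria": {k: float(v) for k, v in result.criteria.items()},
        "trajectory": np.asarray(result.trajectory).tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_fit(path) -> FitResult:
    with open(path) as fh:
        payload = json.load(fh)
    items = ItemSet(a=np.array(payload["items"]["a"]),
                    b=np.array(payload["items"]["b"]),
                    c=np.array(payload["items"]["c"]))
    dinfo = payload["density"]
    grid = build_grid(dinfo["lo"], dinfo["hi"], dinfo["step"])
    eta = payload["eta"]
    spec = payload["spline"]
    if eta is not None and spec["knots"] is not None:
        basis = build_basis(grid, spec["knots"], spec["degree"])
        density: RamsayDensity | np.ndarray = ramsay_pdf(basis, np.array(eta))
    else:
        density = np.array(dinfo["mass"])
    return FitResult(
        items=items,
        eta=None if eta is None else np.array(eta),
        density=density,
        converged=payload["converged"],
        iterations=payload["iterations"],
        marginal_loglik=payload["marginal_loglik"],
        n_params=payload["n_params"],
        criteria=payload["criteria"],
        trajectory=np.array(payload["trajectory"]),
    )
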