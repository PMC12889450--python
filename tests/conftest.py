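import logging

import numpy as np
import pytest

from organelletrack.pipeline import RunConfig, run_pipeline
from organelletrack.stack_io import write_stack
from organelletrack.synthetic import generate_stack, get_preset

logging.getLogger("organelletrack").setLevel(logging.ERROR)


def raster_disc(shape, center, radius):
    """Boolean disc: pixel centres within radius of (x, y) center."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2


def raster_ellipse(shape, center, a, b, theta=0.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dx, dy = xx - center[0], yy - center[1]
    c, s = np.cos(theta), np.sin(theta)
    u = dx * c - dy * s
    v = dx * s + dy * c
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


# ---------------------------------------------------------------- oracles


def flood_fill_label(mask):
    """Independent 8-connected component labelling by BFS flood fill."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if not mask[r, c] or labels[r, c]:
                continue
            current += 1
            queue = [(r, c)]
            labels[r, c] = current
            while queue:
                y, x = queue.pop()
                for dy in (-1, 0, 1):
                    for dx in (-1, 0, 1):
                        yy, xx = y + dy, x + dx
                        if (
                            0 <= yy < mask.shape[0]
                            and 0 <= xx < mask.shape[1]
                            and mask[yy, xx]
                            and not labels[yy, xx]
                        ):
                            labels[yy, xx] = current
                            queue.append((yy, xx))
    return labels, current


def greedy_assignment_oracle(prev, nxt, max_dist):
    """Exhaustive minimum-distance greedy matching: repeatedly take the
    globally closest unmatched (prev, next) pair within max_dist."""
    assign = [-1] * len(nxt)
    used_prev, used_next = set(), set()
    pairs = sorted(
        (float(np.hypot(p[0] - q[0], p[1] - q[1])), i, j)
        for i, p in enumerate(prev)
        for j, q in enumerate(nxt)
    )
    for d, i, j in pairs:
        if d > max_dist:
            break
        if i in used_prev or j in used_next:
            continue
        assign[j] = i
        used_prev.add(i)
        used_next.add(j)
    return assign


def coloc_by_counting(a, b):
    """Per-pixel counting oracle for all four colocalization metrics."""
    n11 = n10 = n01 = n00 = 0
    for pa, pb in zip(np.asarray(a, bool).ravel(), np.asarray(b, bool).ravel()):
        if pa and pb:
            n11 += 1
        elif pa:
            n10 += 1
        elif pb:
            n01 += 1
        else:
            n00 += 1
    na, nb = n11 + n10, n11 + n01
    m1 = n11 / na if na else 0.0
    m2 = n11 / nb if nb else 0.0
    union = n11 + n10 + n01
    pct = 100.0 * n11 / union if union else 0.0
    n = na + nb - n11 + n00
    if na in (0, n) or nb in (0, n):
        phi = float("nan")
    else:
        phi = (n * n11 - na * nb) / np.sqrt(float(na) * (n - na) * nb * (n - nb))
    return m1, m2, phi, pct


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def counting_run(tmp_path_factory):
    """Full pipeline run on the 'counting' preset (shared across tests)."""
    root = tmp_path_factory.mktemp("counting")
    spec = get_preset("counting")
    stack, gt = generate_stack(spec, path=root / "stack.tif")
    out = root / "out"
    cfg = RunConfig(input_path=str(root / "stack.tif"), output_dir=str(out))
    manifest = run_pipeline(cfg)
    return {"spec": spec, "gt": gt, "out": out, "manifest": manifest}


@pytest.fixture(scope="session")
def two_condition_runs(tmp_path_factory):
    """Pipeline outputs for the slow/fast preset pair (comparison tests)."""
    root = tmp_path_factory.mktemp("conditions")
    dirs = {}
    for name in ("two-conditions-slow", "two-conditions-fast"):
        spec = get_preset(name)
        stack, _ = generate_stack(spec, path=root / f"{name}.tif")
        out = root / name
        run_pipeline(RunConfig(input_path=str(root / f"{name}.tif"), output_dir=str(out)))
        dirs[name.rsplit("-", 1)[1]] = out
    return dirs
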