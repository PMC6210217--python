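"""Shared helper: cross-check median polish against R stats::medpolish."""

import shutil
import subprocess

import numpy as np

from diaforge.quant import median_polish

HAVE_R = shutil.which("Rscript") is not None

_R_SCRIPT = """
d <- read.table(commandArgs(TRUE)[1], col.names=c("i","r","c","v"))
out <- file(commandArgs(TRUE)[2], "w")
for (i in sort(unique(d$i))) {
  s <- d[d$i == i,]
  m <- matrix(0, max(s$r)+1, max(s$c)+1)
  m[cbind(s$r+1, s$c+1)] <- s$v
  mp <- medpolish(m, eps=1e-12, maxiter=200, trace.iter=FALSE)
  writeLines(paste(c(i, sprintf("%.12g", mp$overall + mp$col)), collapse="\t"), out)
}
close(out)
"""


def random_small_matrices(seed: int, n: int = 50):
    rng = np.random.default_rng(seed)
    mats = []
    for _ in range(n):
        nr = int(rng.integers(2, 7))
        nc = int(rng.integers(2, 9))
        mats.append(rng.normal(10, 3, size=(nr, nc)).round(6))
    return mats


def max_diff_vs_r_medpolish(mats, tmp_path) -> float:
    """Largest |overall+col difference| between our polish and R's, any matrix."""
    lines = []
    for i, m in enumerate(mats):
        for r in range(m.shape[0]):
            for c in range(m.shape[1]):
                lines.append(f"{i}\t{r}\t{c}\t{m[r, c]:.10g}")
    (tmp_path / "mats.tsv").write_text("\n".join(lines) + "\n")
    (tmp_path / "polish.R").write_text(_R_SCRIPT)
    subprocess.run(
        [
            "Rscript",
            str(tmp_path / "polish.R"),
            str(tmp_path / "mats.tsv"),
            str(tmp_path / "out.tsv"),
        ],
        check=True,
        capture_output=True,
    )
    ref = {}
    for line in (tmp_path / "out.tsv").read_text().splitlines():
        parts = line.split("\t")
        ref[int(float(parts[0]))] = np.array([float(x) for x in parts[1:]])
    worst = 0.0
    for i, m in enumerate(mats):
        overall, _row, col, _res = median_polish(m, max_iter=200, tol=1e-12)
        worst = max(worst, float(np.abs(overall + col - ref[i]).max()))
    return worst
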