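"""Run manifests: config snapshot, seed, versions, and output digests."""

from __future__ import annotations

import hashlib
import time
from pathlib import Path

import yaml

MANIFEST_NAME = "manifest.yaml"


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _versions() -> dict[str, str]:
    import numpy
    import pandas
    import sklearn

    from . import __version__

    return {
        "wristfunc": __version__,
        "numpy": numpy.__version__,
        "pandas": pandas.__version__,
        "scikit-learn": sklearn.__version__,
    }


def write_manifest(
    outdir: str | Path,
    stage: str,
    config: dict,
    seed: int | None,
    outputs: list[str | Path] | None = None,
) -> Path:
    """Write (or extend) the single manifest in *outdir* for this stage."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / MANIFEST_NAME
    doc: dict = {}
    if path.exists():
        doc = yaml.safe_load(path.read_text()) or {}
    doc.setdefault("stages", {})
    doc["stages"][stage] = {
        "config": config,
        "seed": seed,
        "versions": _versions(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "outputs": {
            str(Path(p).relative_to(outdir)): _digest(Path(p))
            for p in (outputs or [])
        },
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def verify_manifest(outdir: str | Path) -> bool:
    """Re-hash every recorded output; True when all digests match."""
    outdir = Path(outdir)
    doc = yaml.safe_load((outdir / MANIFEST_NAME).read_text())
    for stage in doc.get("stages", {}).values():
        for rel, digest in stage.get("outputs", {}).items():
            if _digest(outdir / rel) != digest:
                return False
    return True
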