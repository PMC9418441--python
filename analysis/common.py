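"""Shared paths and the study configuration for the analysis scripts."""

from pathlib import Path

from ripedit.pipeline import RunConfig

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "results" / "data"
RESULTS = ROOT / "results"

#: one configuration shared by every script: a 30-gene synthetic genome with
#: 40 planted editing sites (12 differential), 400 genes in the RIP matrix
#: (40 planted bound at ratio of ratios 4), 3 replicates throughout
CONFIG = RunConfig(seed=20260928)


def require(path: Path, hint: str) -> Path:
    if not path.exists():
        raise SystemExit(f"missing {path}; run {hint} first")
    return path
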