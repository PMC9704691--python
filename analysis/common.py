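"""Shared input loading for the numbered analysis scripts.

Script 01 writes the study panels under results/panels/; later scripts load
them from there, so the whole sequence is reproducible from the recorded
files alone."""

from pathlib import Path

from gelamatch.data_model import AnalysisConfig, read_fst_matrix, read_panel

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
PANELS = RESULTS / "panels"

SEED = 1


def load_panel(name="scenario"):
    d = PANELS / name
    panel = read_panel(d / "populations.tsv")
    fst = read_fst_matrix(d / "fst_matrix.tsv", panel)
    return panel, fst


def analysis_config(seed=SEED):
    return AnalysisConfig(rng_seed=seed)
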