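"""Built-in worked-example formulations.

These encode the published worked examples the scoring method was
demonstrated on — two complementary 100 mg demonstration mixes, three
clinical-trial extracts (a soy OTC preparation, a red-clover extract
and a soy-germ dose), a nine-trial comparison set, and the two
single-compound genistein dose cases that anchor the relevance
threshold.  All intakes are aglycone-equivalent mg/day as reported.
Everything is generated programmatically so the test suite and the CLI
demos need no external data.
"""

from __future__ import annotations

from pathlib import Path

from .affinity import default_affinity_table, dump_affinity_table
from .formio import write_formulations
from .scoring import Formulation, FormulationComponent

__all__ = ["builtin_formulations", "generate_fixtures", "FIXTURE_FILES"]


def _form(label: str, components: list[tuple[str, float]], annotation: str | None = None) -> Formulation:
    return Formulation(
        label,
        tuple(FormulationComponent(name, mg) for name, mg in components),
        annotation,
    )


def builtin_formulations() -> dict[str, list[Formulation]]:
    """All built-in formulations, grouped by fixture set name."""
    return {
        "demo_assays": [
            _form("assay-1", [("daidzein", 25), ("genistein", 75)]),
            _form("assay-2", [("daidzein", 75), ("genistein", 25)]),
        ],
        "soy_otc": [
            _form(
                "soy-otc-60mg",
                [("daidzein", 12), ("glycitein", 1.26), ("genistein", 45)],
                "about 50% reduction in hot flushes",
            ),
        ],
        "red_clover": [
            _form(
                "red-clover-43.5mg",
                [
                    ("daidzein", 0.1),
                    ("formononetin", 16),
                    ("genistein", 1),
                    ("biochanin a", 26),
                ],
                "non-significant effect on bone density",
            ),
        ],
        # The soy-germ dose pools daidzein + glycitein into one daidzein
        # entry: the two share affinities under the proxy rule, so the
        # pooling is lossless for scoring.
        "soy_germ": [
            _form(
                "soy-germ-60g",
                [("daidzein", 1206), ("genistein", 185)],
                "attenuation of bone loss",
            ),
        ],
        "trial_comparison": [
            _form("trial-25", [("genistein", 50)], "24% reduction in hot flushes"),
            _form(
                "trial-26",
                [("genistein", 54)],
                "3% increase in BMD; increased bone formation; decreased bone resorption",
            ),
            _form(
                "trial-27-28",
                [("genistein", 54)],
                "increased nitrites/nitrates; increased brachial artery FMD; decreased endothelin-1",
            ),
            _form(
                "trial-29",
                [("genistein", 48), ("daidzein", 24), ("glycitein", 8)],
                "increased FMD",
            ),
            _form(
                "trial-30",
                [("genistein", 40.9), ("daidzein", 40.9), ("glycitein", 8.2)],
                "no change in FMD; increased endothelium-independent vasodilation",
            ),
            _form("trial-31a", [("biochanin a", 80)], "no change in FMD"),
            _form("trial-31b", [("formononetin", 80)], "no change in FMD"),
            _form(
                "trial-32",
                [
                    ("genistein", 4),
                    ("daidzein", 3.5),
                    ("biochanin a", 24.5),
                    ("formononetin", 8),
                ],
                "increased arterial compliance",
            ),
            _form(
                "trial-33",
                [("genistein", 76), ("daidzein", 37), ("glycitein", 5)],
                "increased arterial compliance; no change in FMD",
            ),
        ],
        "genistein_dose_cases": [
            _form("genistein-10mg", [("genistein", 10)]),
            _form("genistein-15mg", [("genistein", 15)]),
        ],
    }


FIXTURE_FILES = tuple(sorted(builtin_formulations())) + ("affinity_default",)


def generate_fixtures(output_dir: str | Path) -> list[Path]:
    """Write every fixture set as a CSV, plus the default affinity table as YAML.

    Regeneration is deterministic: running twice produces byte-identical
    files.  Returns the written paths.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, forms in sorted(builtin_formulations().items()):
        path = out / f"{name}.csv"
        write_formulations(forms, path)
        written.append(path)
    affinity_path = out / "affinity_default.yaml"
    affinity_path.write_text(dump_affinity_table(default_affinity_table()), encoding="utf-8")
    written.append(affinity_path)
    return written
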