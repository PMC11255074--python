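"""Model/Results facade over the cohort-size experiment.

`CohortSizeModel` bundles the patients, the healthy cohort and the
experiment configuration; `fit()` runs the full subsampling experiment and
returns a `CohortSizeResults` carrying per-patient consistency curves, knee
points, the knee-point summary (max, mean±SD, median, IQR) and plotting /
summary-table helpers, in the spirit of statsmodels results objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .consistency import ConsistencyCurve, ExperimentConfig, run_experiment
from .io import write_curve
from .knee import KneePoint


class CohortSizeModel:
    """How many healthy subjects does a normal template need?

    Parameters
    ----------
    patients
        List of ``(SubjectRecord, GMVolume)`` pairs for the patients whose
        atrophy maps are being stabilized.
    cohort
        Metadata records of the healthy pool.
    cohort_volumes
        Mapping subject_id -> GMVolume for every healthy subject.
    config
        :class:`~normmap.consistency.ExperimentConfig`; defaults mirror the
        reference protocol (n = 3..100, 100 repeats, ±2-year matching).
    smoothing
        Spline smoothing for knee detection (None = automatic by GCV).
    """

    def __init__(self, patients, cohort, cohort_volumes,
                 config: ExperimentConfig | None = None,
                 smoothing: float | None = None):
        self.patients = list(patients)
        self.cohort = list(cohort)
        self.cohort_volumes = dict(cohort_volumes)
        self.config = config or ExperimentConfig()
        self.smoothing = smoothing

    @classmethod
    def from_directory(cls, cohort_dir, table_path, patients,
                       config=None, smoothing=None):
        """Build from a cohort directory: a CSV table whose ``volume_ref``
        column names NIfTI files relative to ``cohort_dir``."""
        from pathlib import Path

        from .io import read_cohort_table, read_volume

        cohort = read_cohort_table(table_path)
        volumes = {
            r.subject_id: read_volume(Path(cohort_dir) / r.volume_ref)
            for r in cohort
        }
        return cls(patients, cohort, volumes, config=config, smoothing=smoothing)

    def fit(self) -> "CohortSizeResults":
        results, summary = run_experiment(
            self.patients,
            self.cohort,
            self.cohort_volumes,
            self.config,
            smoothing=self.smoothing,
        )
        return CohortSizeResults(model=self, results=results, knee_summary=summary)


@dataclass
class CohortSizeResults:
    """Fitted cohort-size experiment: curves, knees and their summary."""

    model: CohortSizeModel
    results: list  # (SubjectRecord, ConsistencyCurve, KneePoint)
    knee_summary: dict

    @property
    def curves(self) -> list[ConsistencyCurve]:
        return [curve for _, curve, _ in self.results]

    @property
    def knees(self) -> list[KneePoint]:
        return [knee for _, _, knee in self.results]

    @property
    def min_required_subjects(self) -> int:
        """The experiment's headline estimate: the maximum knee point."""
        return self.knee_summary["max"]

    def sd_spatial_at(self, n: int) -> np.ndarray:
        """SD̄_spatial of every patient's curve at template size n."""
        out = []
        for _, curve, _ in self.results:
            idx = {nn: v for nn, v in curve.points}
            if n not in idx:
                raise KeyError(f"template size {n} not in curve")
            out.append(idx[n])
        return np.array(out)

    def save_curves(self, directory) -> None:
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for _, curve, _ in self.results:
            write_curve(curve, directory / f"curve_{curve.patient_id}.csv")

    def summary(self) -> str:
        """Plain-text summary table of per-patient knees and the headline
        minimum template size."""
        s = self.knee_summary
        lines = [
            "Normal-cohort size experiment",
            "=" * 64,
            f"patients: {len(self.results)}    "
            f"template sizes: {self.model.config.n_min}..{self.model.config.n_max}    "
            f"repeats: {self.model.config.repeats}",
            "-" * 64,
            f"{'patient':<16}{'sex':<8}{'age':>4}  {'knee n':>7}  {'distance':>9}",
        ]
        for record, _, knee in self.results:
            kn = str(knee.n_at_knee) if knee.found else "-"
            lines.append(
                f"{record.subject_id:<16}{record.sex:<8}{record.age:>4}"
                f"  {kn:>7}  {knee.distance:>9.4f}"
            )
        q1, q3 = s["iqr"]
        lines += [
            "-" * 64,
            f"knee points: max {s['max']}, mean {s['mean']:.1f} ± {s['sd']:.1f}, "
            f"median {s['median']:.0f}, IQR {q1:.0f}-{q3:.0f}",
            f"minimum subjects for consistent atrophy estimation: {s['max']}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, mark_max_knee: bool = True):
        """Consistency curves for all patients, knee of each marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for record, curve, knee in self.results:
            ax.plot(curve.n_values, curve.sd_values, alpha=0.7,
                    label=record.subject_id)
            if knee.found:
                idx = list(curve.n_values).index(knee.n_at_knee)
                ax.plot(knee.n_at_knee, curve.sd_values[idx], "ko", ms=4)
        if mark_max_knee:
            ax.axvline(self.knee_summary["max"], ls="--", color="k", lw=1)
        ax.set_xlabel("subjects in normal template (n)")
        ax.set_ylabel(r"$\overline{SD}_{spatial}$ of z-scores")
        ax.set_title("Template-subsampling consistency")
        return ax
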