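"""End-to-end glue: raw simulated session -> df/f -> detected events ->
per-condition NeuronRecords ready for population statistics.

This is the desk-scale equivalent of the full imaging analysis: filter each
neuron's trace, normalize to the 10th-percentile f0, subtract the slow
baseline, detect 3xSD transients, and summarise rates per condition epoch.
"""

from __future__ import annotations

import pandas as pd

from .events import DetectionConfig, detect_transients
from .simulate import SimulatedSession
from .stats import NeuronRecord, RecordingSession
from .traces import compute_dff, lowpass_filter, time_dependent_baseline

CALCIUM_LOWPASS_HZ = 10.0
GLUTAMATE_LOWPASS_HZ = 40.0


def process_session(
    sim: SimulatedSession,
    detection: DetectionConfig | None = None,
    lowpass: float = CALCIUM_LOWPASS_HZ,
) -> RecordingSession:
    """Quantify a simulated session into paired per-condition records.

    Events are detected once on each neuron's full trace and assigned to the
    condition epoch containing their onset; the per-condition rate is
    60 x count / epoch duration.
    """
    detection = detection or DetectionConfig()
    records: dict[str, list[NeuronRecord]] = {e.label: [] for e in sim.conditions}
    for i, trace in enumerate(sim.traces):
        dff = compute_dff(lowpass_filter(trace, lowpass), mode="trace-percentile")
        dff.baseline_curve = time_dependent_baseline(dff, window=detection.baseline_window)
        events = detect_transients(dff, detection)
        for epoch in sim.conditions:
            in_epoch = [e for e in events if epoch.start <= e.onset_time < epoch.end]
            rate = 60.0 * len(in_epoch) / (epoch.end - epoch.start)
            records[epoch.label].append(
                NeuronRecord(neuron_id=i + 1, condition=epoch.label, rate=rate,
                             events=in_epoch)
            )
    return RecordingSession(
        subject_id=sim.subject_id, genotype=sim.genotype, treatment=sim.treatment,
        records=records,
    )


def session_table(session: RecordingSession) -> pd.DataFrame:
    """Long-format per-neuron table (one row per neuron x condition)."""
    rows = [
        {
            "subject_id": session.subject_id,
            "genotype": session.genotype,
            "treatment": session.treatment,
            "condition": condition,
            "neuron_id": rec.neuron_id,
            "rate_per_min": rec.rate,
            "hyperactive": rec.hyperactive,
            "auc": rec.auc,
        }
        for condition, recs in session.records.items()
        for rec in recs
    ]
    return pd.DataFrame(rows)
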