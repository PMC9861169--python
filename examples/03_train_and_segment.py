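"""Train the per-scan pixel classifier and segment object from air.

Two 10x10 square ROIs from the scan itself — one on a sample tube
(labelled 1), one on aerated background (labelled 0) — provide the 200
training vectors. The 23-10-1 network then classifies every pixel's
intensity-vs-TR vector.

Pick the object ROI on the weakest-signal sample present (the slowest
recovery for T1 work, the shortest T2 for T2 work) so every other sample
lies between the two training classes rather than beyond them.
"""

from relaxmap import (
    RoiSquare,
    classify_pixels,
    default_phantom_spec,
    extract_training_set,
    render_series,
    t1_protocol,
    train_classifier,
)

series, truth = render_series(default_phantom_spec(seed=1), t1_protocol())
object_roi = RoiSquare(91, 91, 10)  # inside the dim, slow water-like tube
air_roi = RoiSquare(2, 54, 10)      # empty space

ts = extract_training_set(series, object_roi, air_roi)
print(f"training set: {ts.n_vectors} vectors of length {ts.n_inputs}")

model, report = train_classifier(ts, hidden=10, seed=1)
print(f"trained in {report.n_epochs} epochs, final loss {report.final_loss:.2e}, "
      f"training accuracy {report.training_accuracy:.3f}")

mask = classify_pixels(series, model, threshold=0.5)
agreement = (mask == truth.mask).mean()
print(f"mask retains {mask.mean():.1%} of pixels; "
      f"agreement with ground truth {agreement:.2%}")
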