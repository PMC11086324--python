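# semg-motionmap

Mapping human arm motion from surface electromyography (sEMG).  The package
implements a complete desk-scale pipeline for myoelectric intent
recognition:

* **Signal conditioning** — zero-phase Butterworth band-limiting
  (20 Hz high-pass, 200 Hz low-pass), 50 Hz mains notch, sliding-window
  MAV/RMS amplitude features, moving-average smoothing and per-channel
  min–max ("interval scaling") normalisation to [0, 1].
* **Gesture recognition** — a hybrid classifier over 8 × 200
  (channel × time) armband windows: three time-only convolutions and two
  poolings (kernels never mix channels) produce (128, 5, 8) feature maps →
  a 5120-vector, concatenated with 24 handcrafted features (per-channel
  RMS, mean and median frequency) and fed to two fully connected layers
  yielding score vectors for four gestures (clench, relax, palm-up,
  palm-down).  Implemented directly in numpy with explicit
  backpropagation; trained by mini-batch SGD with learning rate
  0.00681292, dropout 0.5, batch size 128.
* **Joint-angle regression** — one 8-20-1 backpropagation network per
  degree of freedom, mapping 7 normalised muscle features + normalised
  motion time to an angle in degrees.  Training uses the classic momentum
  update Δw(k+1) = (1−mc)·η·δ·p + mc·Δw(k) and the multiplicative
  adaptive learning rate
  η ← 1.05η if SSE↓, η ← 0.7η if SSE > 1.04·SSE_prev, else unchanged,
  on the weighted error E = (1/n)·Σ wᵢ(yᵢ−ŷᵢ)².
* **IMU kinematics** — quaternion streams from chest/upper-arm/forearm
  sensors are zero-calibrated against the chest unit and decomposed into
  shoulder (abduction, flexion, rotation) and elbow (flexion, forearm
  rotation) angles.
* **Action mapping** — a deterministic state machine translating debounced
  gestures into robot commands: clench → claw close, relax → claw open,
  palm-up → emergency stop (suppresses all joint commands), palm-down →
  resume.
* **Synthetic data** — protocol-faithful generators (3 s hold / 5 s rest /
  5 repetitions; joint ranges: shoulder 0–90° per axis, elbow 0–120°,
  forearm −30–150°) driving a 7 × 5 muscle-synergy model and an
  amplitude-modulated band-limited Gaussian EMG carrier with 50 Hz mains,
  drift and sensor noise, plus matching IMU quaternion streams.

Estimators follow scikit-learn conventions (`fit` / `predict` /
`predict_proba`, `get_params`, trailing-underscore fitted attributes) and
compose with sklearn model selection.

## Worked example

```python
from sklearn.model_selection import train_test_split

from semg_motionmap.synthetic_data import gen_gesture_dataset
from semg_motionmap import HybridGestureClassifier, GestureNetConfig
from semg_motionmap.gesture_recognition import evaluate_confusion, GestureDataset

data = gen_gesture_dataset(n_per_class=50, overlap=0.3, seed=11)
X_tr, X_te, y_tr, y_te = train_test_split(
    data.windows, data.labels, test_size=0.25, random_state=11, stratify=data.labels
)
model = HybridGestureClassifier(GestureNetConfig(seed=11, epochs=15)).fit(X_tr, y_tr)
cm = evaluate_confusion(model, GestureDataset(X_te, y_te))
print(round(cm.accuracy, 3))
print({k: round(v, 3) for k, v in cm.per_class_rates.items()})
```

prints

```
1.0
{'clench': 1.0, 'relax': 1.0, 'palm_up': 1.0, 'palm_down': 1.0}
```

i.e. on held-out synthetic windows with moderate palm-up/palm-down template
overlap the hybrid classifier separates all four gestures; at higher
overlap the residual confusion concentrates on the two palm gestures.

The same pipelines are scriptable:

```bash
semg-motionmap simulate gestures --n 200 --overlap 0.3 --seed 11 --out data/
semg-motionmap train-gesture --manifest data/manifest.csv --out model
semg-motionmap eval-gesture --model model --manifest data/manifest.csv --report report.json
semg-motionmap run --config src/semg_motionmap/configs/experiment_gesture.yaml --report report.json
```

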