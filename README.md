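# fesloop

A hardware-free simulator and control library for a 4-channel closed-loop
electrostimulator. It reproduces, at desk scale, the full control stack of
such a device — biphasic stimulation waveform scheduling, a boost-converter
voltage model, dual PID controllers with conditional-integration anti-windup
and hard output saturation, agonist/antagonist muscle-channel routing, and
complementary-filter joint-angle estimation — closed around a synthetic
two-degree-of-freedom ankle plant so that every component is testable without
hardware or subjects.

## Layout

| Module | What it does |
| --- | --- |
| `fesloop.waveform` | Biphasic pulse schedules (exact integer-microsecond timing), measured timing stats, boost-converter dynamics, waveform rendering, CSV I/O |
| `fesloop.orientation` | Accelerometer tilt + gyro integration fused with a single-coefficient complementary filter; IMU stream CSV I/O |
| `fesloop.pid` | Discrete PID (backward-Euler integral, raw derivative) with conditional integration and output clamping |
| `fesloop.selector` | Signed control action → agonist/antagonist duty routing (mutually exclusive by construction) |
| `fesloop.plant` | Synthetic ankle: two uncoupled second-order joints, motor-threshold deadzone / recruitment-saturation duty→torque map, activation lag, noise and disturbance models, IMU emitter |
| `fesloop.session` | Closed-loop orchestration (sense → fuse → PID ×2 → route → stimulate), sequential protocol setpoints, step-response tuning metrics, per-phase tracking metrics |
| `fesloop.cli_io` | YAML config parsing with aggregated validation, run manifests, fixture generation |

## CLI

```sh
fesloop open-loop --frequency-hz 50 --pulse-duration-us 200 --duty-pct 5 \
    --duration-s 10 --out schedule.csv      # fixed-parameter stimulation schedule
fesloop closed-loop --seed 1 --out run/     # full simulated session (log + metrics)
fesloop tune --dof sagittal --step-deg 10 --kp 2,4,8 --ki 0,2,4 --out tune.csv
fesloop protocol                            # print the default setpoint profile
fesloop fixtures --seed 0 --out fixtures/   # reference input files
```

`closed-loop` without `--config` uses the shipped reference configuration:
100 Hz control loop, 50 Hz / 200 µs / 5 % stimulation baseline on all four
channels, and the published PI gains (sagittal kp 8.2, ki 3.8, limits
[−14, 10]; frontal kp 8.1, ki 3.2, limits [−12, 14]). Every CLI run writes a
JSON manifest (tool version, config digest, seed, outputs) next to its
outputs, and identical config + seed reproduce outputs bit-identically.

## Notes on the plant

The reference plant (`fesloop.plant.default_plant`) is deliberately the
simplest model exhibiting the nonlinearities the controller must survive:
deadzone (motor threshold at 3 % duty), recruitment saturation (14 % duty),
first-order activation lag, second-order overdamped joint dynamics with hard
stops, and optional Gaussian measurement noise and disturbance torques (off
by default so reference runs are deterministic). Mechanical parameters use
per-degree units so the static balance `angle = rest + torque/stiffness`
reads directly in degrees; all values live in config, not code.
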