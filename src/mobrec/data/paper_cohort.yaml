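# Calibrated study-scale cohort: 13 patients (6 anterior / 7 posterior),
# 70-day follow-up; trajectories solved from the pooled week-1/week-5
# mobility targets; PROM linkage targets the reported correlations.
n_anterior: 6
n_posterior: 7
follow_up_days: 70
plateau_day: 45
trajectories:
  distance_km:
    anterior:
    - 0.8889316621918315
    - 0.05426113004814721
    posterior:
    - 0.8889316621918315
    - 0.05426113004814721
  home_hours:
    anterior:
    - 14.335934065934067
    - -0.034175824175824196
    posterior:
    - 15.035934065934068
    - -0.009175824175824219
  sig_loc_count:
    anterior:
    - 0.30617737110990684
    - 0.022972644421900952
    posterior:
    - 0.09426562314461216
    - 0.020224035809896367
  sig_loc_entropy:
    anterior:
    - -2.3087282447721194
    - 0.03412540875097986
    posterior:
    - -2.5710925092396106
    - 0.034125408750979865
  steps:
    anterior:
    - 4.893044695134456
    - 0.022544652027984315
    posterior:
    - 4.183526336792048
    - 0.03895652093435718
n_places: 4
place_radii_km:
- 0.5
- 1.2
- 2.5
- 4.0
gps_on_s: 60.0
gps_off_s: 240.0
gps_hz: 1.0
gps_noise_sd_m: 3.0
accel_on_s: 10.0
accel_off_s: 10.0
accel_hz: 10.0
idle_burst_keep: 0.02
cadence_hz: 1.8
step_amplitude_g: 0.28
accel_noise_g: 0.02
transit_speed_ms: 8.0
walk_speed_ms: 1.3
ambient_speed_ms: 2.0
ambient_dwell_min_s: 120.0
ambient_dwell_max_s: 600.0
indoor_min_s: 2420.0
indoor_shoulder_s: 260.0
ambient_hop_min_m: 60.0
ambient_hop_max_m: 1200.0
align_hops_to_gaps: true
night_start_h: 20.0
night_end_h: 8.0
visit_noise_sd: 0.1
sigma_patient: 0.12
sigma_day: 0.3
day_loading: 0.7
home_sigma_patient_h: 0.35
home_sigma_day_h: 0.45
home_day_loading: -0.65
count_sigma_day: 0.12
count_day_loading: 0.5
home_min_h: 10.5
home_max_h: 20.5
day_missing_prob: 0.1
render_sensors: true
vas_response_prob: 0.52
weekly_response_prob:
  mJOA: 0.71
  ODI: 0.74
  NDI: 0.69
prom_links:
  VAS:
  - distance_km
  - -0.358
  - 4.0
  - 2.2
  mJOA:
  - steps
  - 0.403
  - 13.5
  - 1.5
  ODI:
  - distance_km
  - -0.409
  - 27.0
  - 12.0
  NDI:
  - distance_km
  - -0.279
  - 24.0
  - 11.0
timezone: Europe/Rome
first_surgery_date: '2023-04-03'
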