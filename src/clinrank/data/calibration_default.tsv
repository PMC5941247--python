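# Shipped per-class calibration constants for the predicted-significance ranges.
# Derived from the published two-star control summary (control group sizes,
# medians and prediction intervals); zero-side PI endpoints equal the analytic
# fixed bounds 2*w*0.7. Recalibrate with clinrank.calibration.calibrate() and
# save_calibration_stats() to replace.
significance	n	median	pi_low	pi_high	confidence_pct
B	4755	-12.6	-40.2	-8.4	95.0
LB	5233	-6	-26.7	-4.2	99.5
US	14011	-0.6	-2.6	-0.4	99.5
LP	502	5.7	4.2	14.7	96.0
P	3586	12	8.4	44.4	96.0
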