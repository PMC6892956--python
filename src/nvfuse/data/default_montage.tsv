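label	modality	x	y	z	roi
Fp1	eeg	-29.4	83.9	-7.0	L-FP
AF7	eeg	-54.8	68.6	-10.6	L-dlPFC
AF3	eeg	-26.0	64.0	23.0	L-dlPFC
F1	eeg	-27.5	56.9	60.3	L-FP
F3	eeg	-50.2	53.1	42.2	L-dlPFC
F5	eeg	-64.5	48.0	16.9	L-dlPFC
F7	eeg	-70.3	42.5	-11.4	other
FT7	eeg	-80.8	14.1	-11.1	other
FC5	eeg	-77.2	18.6	24.5	other
FC3	eeg	-60.2	22.7	55.5	other
FC1	eeg	-34.1	26.0	80.0	other
C1	eeg	-36.2	-10.0	89.8	other
C3	eeg	-65.4	-11.6	64.4	other
C5	eeg	-80.3	-13.8	29.2	other
T7	eeg	-84.2	-16.0	-9.3	other
TP7	eeg	-84.8	-46.0	-7.1	other
CP5	eeg	-79.6	-46.6	30.9	other
CP3	eeg	-63.6	-47.0	65.6	other
CP1	eeg	-35.5	-47.3	91.3	other
P1	eeg	-28.6	-80.5	75.4	other
P3	eeg	-53.0	-78.8	55.9	other
P5	eeg	-67.3	-76.3	28.4	other
P7	eeg	-72.4	-73.5	-2.5	other
P9	eeg	-73.0	-73.8	-41.0	other
PO7	eeg	-54.8	-97.5	2.8	other
PO3	eeg	-36.5	-100.9	37.2	other
O1	eeg	-29.4	-112.4	8.8	other
Iz	eeg	0.0	-118.6	-23.1	other
Oz	eeg	0.1	-114.9	14.7	other
POz	eeg	0.2	-102.2	50.6	other
Pz	eeg	0.3	-81.1	82.6	other
CPz	eeg	0.4	-47.3	99.4	other
Fpz	eeg	0.1	88.2	-1.7	L-FP
Fp2	eeg	29.9	84.9	-7.1	R-FP
AF8	eeg	55.7	69.7	-10.8	R-dlPFC
AF4	eeg	31.0	61.0	26.0	R-FP
AFz	eeg	2.0	64.0	27.0	R-FP
Fz	eeg	0.3	58.5	66.5	other
F2	eeg	29.5	57.6	59.5	other
F4	eeg	51.8	54.3	40.8	R-dlPFC
F6	eeg	67.9	49.8	16.4	R-dlPFC
F8	eeg	73.0	44.4	-12.0	other
FT8	eeg	81.8	15.4	-11.3	other
FC6	eeg	79.5	19.9	24.4	other
FC4	eeg	50.0	13.0	51.0	R-dlPFC
FC2	eeg	34.8	26.4	78.8	other
FCz	eeg	0.4	27.4	88.7	other
Cz	eeg	0.4	-9.2	100.2	other
C2	eeg	37.7	-9.6	88.4	other
C4	eeg	67.1	-10.9	63.6	other
C6	eeg	83.5	-12.8	29.2	other
T8	eeg	85.1	-15.0	-9.5	other
TP8	eeg	85.5	-45.5	-7.1	other
CP6	eeg	83.3	-46.1	31.2	other
CP4	eeg	66.6	-46.6	65.6	other
CP2	eeg	38.4	-47.1	90.7	other
P2	eeg	31.9	-80.5	76.7	other
P4	eeg	55.7	-78.6	56.6	other
P6	eeg	67.9	-75.9	28.1	other
P8	eeg	73.1	-73.1	-2.5	other
P10	eeg	73.9	-74.4	-41.2	other
PO8	eeg	55.7	-97.6	2.7	other
PO4	eeg	36.8	-100.8	36.4	other
O2	eeg	29.8	-112.2	8.8	other
HEOG	eog	-55.0	60.0	-20.0	other
VEOG	eog	30.0	75.0	-10.0	other
CH1	fnirs_od	-44.0	41.0	26.0	L-dlPFC
CH2	fnirs_od	-38.0	47.0	34.0	L-dlPFC
CH3	fnirs_od	-32.0	43.0	38.0	L-dlPFC
CH4	fnirs_od	-26.0	64.0	11.0	L-FP
CH5	fnirs_od	-20.0	69.0	17.0	L-FP
CH6	fnirs_od	-14.0	67.0	21.0	L-FP
CH7	fnirs_od	-10.0	62.0	25.0	L-FP
CH8	fnirs_od	14.0	64.0	11.0	R-FP
CH9	fnirs_od	20.0	69.0	17.0	R-FP
CH10	fnirs_od	26.0	65.0	21.0	R-FP
CH11	fnirs_od	32.0	41.0	26.0	R-dlPFC
CH12	fnirs_od	38.0	47.0	34.0	R-dlPFC
CH13	fnirs_od	44.0	43.0	38.0	R-dlPFC
CH14	fnirs_od	48.0	39.0	42.0	R-dlPFC
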