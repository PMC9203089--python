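# Representative base-10 molar extinction coefficients (cm^-1 / M) on a 10 nm
# grid, 400-700 nm.  Columns: oxyhemoglobin, deoxyhemoglobin, bilirubin (bound
# to albumin).  These are smoothed composite values compiled from standard
# optical-spectra references; they are the package's documented defaults and
# may be overridden by the user with a CSV of the same shape.  version=1
wavelength_nm,eps_hbo2,eps_hb,eps_bilirubin
400,266000,223000,28000
410,466000,304000,33000
420,480000,407000,38000
430,247000,529000,43000
440,102000,419000,48000
450,62800,104000,52000
460,44000,81000,55000
470,33200,62000,52000
480,26600,47000,43000
490,23500,39000,30000
500,20900,34000,17000
510,20000,31000,8000
520,24300,29000,3000
530,39500,30500,1000
540,53200,35000,300
550,43500,43000,0
560,33600,53800,0
570,45100,48000,0
580,50100,37000,0
590,14400,28000,0
600,3200,16500,0
610,1500,10500,0
620,980,7800,0
630,700,5900,0
640,510,4700,0
650,390,3750,0
660,320,3200,0
670,290,2800,0
680,280,2550,0
690,280,2300,0
700,290,2000,0
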