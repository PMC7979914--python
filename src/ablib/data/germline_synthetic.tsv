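name	family	chain	segment	cdr_bounds	anchor
IGHV1-2	IGHV1	heavy	V	0,78,78,99,99,150,150,174,174,288	288
IGHV1-18	IGHV1	heavy	V	0,78,78,99,99,150,150,174,174,288	288
IGHV1-46	IGHV1	heavy	V	0,78,78,99,99,150,150,174,174,288	288
IGHV1-69	IGHV1	heavy	V	0,78,78,99,99,150,150,174,174,288	288
IGHV2-5	IGHV2	heavy	V	0,78,78,99,99,150,150,174,174,288	288
IGHV2-26	IGHV2	heavy	V	0,78,78,99,99,150,150,174,174,288	288
IGHV3-7	IGHV3	heavy	V	0,78,78,99,99,150,150,174,174,288	288
IGHV3-23	IGHV3	heavy	V	0,78,78,99,99,150,150,174,174,288	288
IGHV3-30	IGHV3	heavy	V	0,78,78,99,99,150,150,174,174,288	288
IGHV4-59	IGHV4	heavy	V	0,78,78,99,99,150,150,174,174,288	288
IGHV5-51	IGHV5	heavy	V	0,78,78,99,99,150,150,174,174,288	288
IGHV6-1	IGHV6	heavy	V	0,78,78,99,99,150,150,174,174,288	288
IGKV1-5	IGKV1	kappa	V	0,78,78,99,99,150,150,174,174,288	288
IGKV1-9	IGKV1	kappa	V	0,78,78,99,99,150,150,174,174,288	288
IGKV1-33	IGKV1	kappa	V	0,78,78,99,99,150,150,174,174,288	288
IGKV1-39	IGKV1	kappa	V	0,78,78,99,99,150,150,174,174,288	288
IGKV3-11	IGKV3	kappa	V	0,78,78,99,99,150,150,174,174,288	288
IGKV3-20	IGKV3	kappa	V	0,78,78,99,99,150,150,174,174,288	288
IGLV1-40	IGLV1	lambda	V	0,78,78,99,99,150,150,174,174,288	288
IGLV1-47	IGLV1	lambda	V	0,78,78,99,99,150,150,174,174,288	288
IGLV2-14	IGLV2	lambda	V	0,78,78,99,99,150,150,174,174,288	288
IGLV3-1	IGLV3	lambda	V	0,78,78,99,99,150,150,174,174,288	288
IGLV3-21	IGLV3	lambda	V	0,78,78,99,99,150,150,174,174,288	288
IGHJ1	IGHJ	heavy	J		0
IGHJ2	IGHJ	heavy	J		0
IGHJ3	IGHJ	heavy	J		0
IGHJ4	IGHJ	heavy	J		0
IGHJ5	IGHJ	heavy	J		0
IGHJ6	IGHJ	heavy	J		0
IGKJ1	IGKJ	kappa	J		0
IGKJ2	IGKJ	kappa	J		0
IGKJ3	IGKJ	kappa	J		0
IGKJ4	IGKJ	kappa	J		0
IGKJ5	IGKJ	kappa	J		0
IGLJ1	IGLJ	lambda	J		0
IGLJ2	IGLJ	lambda	J		0
IGLJ3	IGLJ	lambda	J		0
IGLJ7	IGLJ	lambda	J		0
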