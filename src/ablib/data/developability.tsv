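gene	class
IGHV1-46	desirable
IGHV1-69	desirable
IGHV1-18	desirable
IGHV1-8	common_in_natural
IGHV1-2	poorly_developable
IGHV1-3	neutral
IGHV1-24	neutral
IGHV1-69-2	neutral
IGHV1-45	neutral
IGHV1-58	neutral
IGHV2-5	common_in_natural
IGHV2-26	common_in_natural
IGHV2-70	common_in_natural
IGHV3-7	desirable
IGHV3-15	desirable
IGHV3-21	desirable
IGHV3-48	desirable
IGHV3-53	desirable
IGHV3-74	desirable
IGHV3-9	common_in_natural
IGHV3-64	common_in_natural
IGHV3-13	neutral
IGHV3-20	neutral
IGHV3-43	neutral
IGHV3-49	neutral
IGHV3-66	neutral
IGHV3-72	neutral
IGHV3-38-3	neutral
IGHV3-73	poorly_developable
IGHV3-11	desirable
IGHV3-30	desirable
IGHV3-33	desirable
IGHV3-30-3	common_in_natural
IGHV3-30-5	common_in_natural
IGHV3-23	desirable
IGHV4-4	desirable
IGHV4-59	common_in_natural
IGHV4-61	common_in_natural
IGHV4-38-2	common_in_natural
IGHV4-34	common_in_natural
IGHV4-28	neutral
IGHV4-30-1	neutral
IGHV4-30-2	neutral
IGHV4-30-4	neutral
IGHV4-31	poorly_developable
IGHV4-39	poorly_developable
IGHV5-10-1	desirable
IGHV5-51	desirable
IGHV6-1	neutral
IGKV1-39	desirable
IGKV1-27	desirable
IGKV1-16	desirable
IGKV1-12	desirable
IGKV1-5	desirable
IGKV1D-39	common_in_natural
IGKV1-33	common_in_natural
IGKV1D-33	common_in_natural
IGKV1D-17	neutral
IGKV1D-16	neutral
IGKV1D-12	neutral
IGKV1-17	poorly_developable
IGKV1-9	desirable
IGKV1-13	neutral
IGKV1D-13	neutral
IGKV1-8	common_in_natural
IGKV1D-43	neutral
IGKV1D-8	neutral
IGKV3-20	desirable
IGKV3-11	desirable
IGKV3-15	desirable
IGKV3D-20	common_in_natural
IGKV3D-11	common_in_natural
IGKV3D-15	common_in_natural
IGLV1-47	desirable
IGLV1-36	common_in_natural
IGLV1-44	common_in_natural
IGLV1-40	desirable
IGLV1-51	desirable
IGLV2-11	desirable
IGLV2-14	desirable
IGLV2-23	desirable
IGLV2-8	common_in_natural
IGLV2-18	common_in_natural
IGLV3-21	desirable
IGLV3-1	poorly_developable
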