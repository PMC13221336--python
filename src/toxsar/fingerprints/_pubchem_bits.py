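"""Bit definitions for the 881-bit PubChem/CACTVS substructure fingerprint.

Three sections: hierarchic element counts (bits 0-114), ring counts
(115-262) over the SSSR ring set, and substructure presence tests
(263-880) expressed as SMARTS.
"""

# (bit, atomic_number, minimum_count)
ELEMENT_BITS = [
    (0, 1, 4),
    (1, 1, 8),
    (2, 1, 16),
    (3, 1, 32),
    (4, 3, 1),
    (5, 3, 2),
    (6, 5, 1),
    (7, 5, 2),
    (8, 5, 4),
    (9, 6, 2),
    (10, 6, 4),
    (11, 6, 8),
    (12, 6, 16),
    (13, 6, 32),
    (14, 7, 1),
    (15, 7, 2),
    (16, 7, 4),
    (17, 7, 8),
    (18, 8, 1),
    (19, 8, 2),
    (20, 8, 4),
    (21, 8, 8),
    (22, 8, 16),
    (23, 9, 1),
    (24, 9, 2),
    (25, 9, 4),
    (26, 11, 1),
    (27, 11, 2),
    (28, 14, 1),
    (29, 14, 2),
    (30, 15, 1),
    (31, 15, 2),
    (32, 15, 4),
    (33, 16, 1),
    (34, 16, 2),
    (35, 16, 4),
    (36, 16, 8),
    (37, 17, 1),
    (38, 17, 2),
    (39, 17, 4),
    (40, 17, 8),
    (41, 19, 1),
    (42, 19, 2),
    (43, 35, 1),
    (44, 35, 2),
    (45, 35, 4),
    (46, 53, 1),
    (47, 53, 2),
    (48, 53, 4),
    (49, 4, 1),
    (50, 12, 1),
    (51, 13, 1),
    (52, 20, 1),
    (53, 21, 1),
    (54, 22, 1),
    (55, 23, 1),
    (56, 24, 1),
    (57, 25, 1),
    (58, 26, 1),
    (59, 27, 1),
    (60, 28, 1),
    (61, 29, 1),
    (62, 30, 1),
    (63, 31, 1),
    (64, 32, 1),
    (65, 33, 1),
    (66, 34, 1),
    (67, 36, 1),
    (68, 37, 1),
    (69, 38, 1),
    (70, 39, 1),
    (71, 40, 1),
    (72, 41, 1),
    (73, 42, 1),
    (74, 44, 1),
    (75, 45, 1),
    (76, 46, 1),
    (77, 47, 1),
    (78, 48, 1),
    (79, 49, 1),
    (80, 50, 1),
    (81, 51, 1),
    (82, 52, 1),
    (83, 54, 1),
    (84, 55, 1),
    (85, 56, 1),
    (86, 71, 1),
    (87, 72, 1),
    (88, 73, 1),
    (89, 74, 1),
    (90, 75, 1),
    (91, 76, 1),
    (92, 77, 1),
    (93, 78, 1),
    (94, 79, 1),
    (95, 80, 1),
    (96, 81, 1),
    (97, 82, 1),
    (98, 83, 1),
    (99, 57, 1),
    (100, 58, 1),
    (101, 59, 1),
    (102, 60, 1),
    (103, 61, 1),
    (104, 62, 1),
    (105, 63, 1),
    (106, 64, 1),
    (107, 65, 1),
    (108, 66, 1),
    (109, 67, 1),
    (110, 68, 1),
    (111, 69, 1),
    (112, 70, 1),
    (113, 43, 1),
    (114, 92, 1),
]

# (bit, ring_class, ring_size, minimum_count); aromatic classes ignore size
RING_BITS = [
    (115, 'any', 3, 1),
    (116, 'sat_carbon', 3, 1),
    (117, 'sat_nitrogen', 3, 1),
    (118, 'sat_hetero', 3, 1),
    (119, 'unsat_carbon', 3, 1),
    (120, 'unsat_nitrogen', 3, 1),
    (121, 'unsat_hetero', 3, 1),
    (122, 'any', 3, 2),
    (123, 'sat_carbon', 3, 2),
    (124, 'sat_nitrogen', 3, 2),
    (125, 'sat_hetero', 3, 2),
    (126, 'unsat_carbon', 3, 2),
    (127, 'unsat_nitrogen', 3, 2),
    (128, 'unsat_hetero', 3, 2),
    (129, 'any', 4, 1),
    (130, 'sat_carbon', 4, 1),
    (131, 'sat_nitrogen', 4, 1),
    (132, 'sat_hetero', 4, 1),
    (133, 'unsat_carbon', 4, 1),
    (134, 'unsat_nitrogen', 4, 1),
    (135, 'unsat_hetero', 4, 1),
    (136, 'any', 4, 2),
    (137, 'sat_carbon', 4, 2),
    (138, 'sat_nitrogen', 4, 2),
    (139, 'sat_hetero', 4, 2),
    (140, 'unsat_carbon', 4, 2),
    (141, 'unsat_nitrogen', 4, 2),
    (142, 'unsat_hetero', 4, 2),
    (143, 'any', 5, 1),
    (144, 'sat_carbon', 5, 1),
    (145, 'sat_nitrogen', 5, 1),
    (146, 'sat_hetero', 5, 1),
    (147, 'unsat_carbon', 5, 1),
    (148, 'unsat_nitrogen', 5, 1),
    (149, 'unsat_hetero', 5, 1),
    (150, 'any', 5, 2),
    (151, 'sat_carbon', 5, 2),
    (152, 'sat_nitrogen', 5, 2),
    (153, 'sat_hetero', 5, 2),
    (154, 'unsat_carbon', 5, 2),
    (155, 'unsat_nitrogen', 5, 2),
    (156, 'unsat_hetero', 5, 2),
    (157, 'any', 5, 3),
    (158, 'sat_carbon', 5, 3),
    (159, 'sat_nitrogen', 5, 3),
    (160, 'sat_hetero', 5, 3),
    (161, 'unsat_carbon', 5, 3),
    (162, 'unsat_nitrogen', 5, 3),
    (163, 'unsat_hetero', 5, 3),
    (164, 'any', 5, 4),
    (165, 'sat_carbon', 5, 4),
    (166, 'sat_nitrogen', 5, 4),
    (167, 'sat_hetero', 5, 4),
    (168, 'unsat_carbon', 5, 4),
    (169, 'unsat_nitrogen', 5, 4),
    (170, 'unsat_hetero', 5, 4),
    (171, 'any', 5, 5),
    (172, 'sat_carbon', 5, 5),
    (173, 'sat_nitrogen', 5, 5),
    (174, 'sat_hetero', 5, 5),
    (175, 'unsat_carbon', 5, 5),
    (176, 'unsat_nitrogen', 5, 5),
    (177, 'unsat_hetero', 5, 5),
    (178, 'any', 6, 1),
    (179, 'sat_carbon', 6, 1),
    (180, 'sat_nitrogen', 6, 1),
    (181, 'sat_hetero', 6, 1),
    (182, 'unsat_carbon', 6, 1),
    (183, 'unsat_nitrogen', 6, 1),
    (184, 'unsat_hetero', 6, 1),
    (185, 'any', 6, 2),
    (186, 'sat_carbon', 6, 2),
    (187, 'sat_nitrogen', 6, 2),
    (188, 'sat_hetero', 6, 2),
    (189, 'unsat_carbon', 6, 2),
    (190, 'unsat_nitrogen', 6, 2),
    (191, 'unsat_hetero', 6, 2),
    (192, 'any', 6, 3),
    (193, 'sat_carbon', 6, 3),
    (194, 'sat_nitrogen', 6, 3),
    (195, 'sat_hetero', 6, 3),
    (196, 'unsat_carbon', 6, 3),
    (197, 'unsat_nitrogen', 6, 3),
    (198, 'unsat_hetero', 6, 3),
    (199, 'any', 6, 4),
    (200, 'sat_carbon', 6, 4),
    (201, 'sat_nitrogen', 6, 4),
    (202, 'sat_hetero', 6, 4),
    (203, 'unsat_carbon', 6, 4),
    (204, 'unsat_nitrogen', 6, 4),
    (205, 'unsat_hetero', 6, 4),
    (206, 'any', 6, 5),
    (207, 'sat_carbon', 6, 5),
    (208, 'sat_nitrogen', 6, 5),
    (209, 'sat_hetero', 6, 5),
    (210, 'unsat_carbon', 6, 5),
    (211, 'unsat_nitrogen', 6, 5),
    (212, 'unsat_hetero', 6, 5),
    (213, 'any', 7, 1),
    (214, 'sat_carbon', 7, 1),
    (215, 'sat_nitrogen', 7, 1),
    (216, 'sat_hetero', 7, 1),
    (217, 'unsat_carbon', 7, 1),
    (218, 'unsat_nitrogen', 7, 1),
    (219, 'unsat_hetero', 7, 1),
    (220, 'any', 7, 2),
    (221, 'sat_carbon', 7, 2),
    (222, 'sat_nitrogen', 7, 2),
    (223, 'sat_hetero', 7, 2),
    (224, 'unsat_carbon', 7, 2),
    (225, 'unsat_nitrogen', 7, 2),
    (226, 'unsat_hetero', 7, 2),
    (227, 'any', 8, 1),
    (228, 'sat_carbon', 8, 1),
    (229, 'sat_nitrogen', 8, 1),
    (230, 'sat_hetero', 8, 1),
    (231, 'unsat_carbon', 8, 1),
    (232, 'unsat_nitrogen', 8, 1),
    (233, 'unsat_hetero', 8, 1),
    (234, 'any', 8, 2),
    (235, 'sat_carbon', 8, 2),
    (236, 'sat_nitrogen', 8, 2),
    (237, 'sat_hetero', 8, 2),
    (238, 'unsat_carbon', 8, 2),
    (239, 'unsat_nitrogen', 8, 2),
    (240, 'unsat_hetero', 8, 2),
    (241, 'any', 9, 1),
    (242, 'sat_carbon', 9, 1),
    (243, 'sat_nitrogen', 9, 1),
    (244, 'sat_hetero', 9, 1),
    (245, 'unsat_carbon', 9, 1),
    (246, 'unsat_nitrogen', 9, 1),
    (247, 'unsat_hetero', 9, 1),
    (248, 'any', 10, 1),
    (249, 'sat_carbon', 10, 1),
    (250, 'sat_nitrogen', 10, 1),
    (251, 'sat_hetero', 10, 1),
    (252, 'unsat_carbon', 10, 1),
    (253, 'unsat_nitrogen', 10, 1),
    (254, 'unsat_hetero', 10, 1),
    (255, 'aromatic', 0, 1),
    (256, 'hetero_aromatic', 0, 1),
    (257, 'aromatic', 0, 2),
    (258, 'hetero_aromatic', 0, 2),
    (259, 'aromatic', 0, 3),
    (260, 'hetero_aromatic', 0, 3),
    (261, 'aromatic', 0, 4),
    (262, 'hetero_aromatic', 0, 4),
]

# (bit, SMARTS); bit is set when the pattern occurs at least once
SMARTS_BITS = [
    (263, '[Li&!H0]'),
    (264, '[Li]~[Li]'),
    (265, '[Li]~[#5]'),
    (266, '[Li]~[#6]'),
    (267, '[Li]~[#8]'),
    (268, '[Li]~[F]'),
    (269, '[Li]~[#15]'),
    (270, '[Li]~[#16]'),
    (271, '[Li]~[Cl]'),
    (272, '[#5&!H0]'),
    (273, '[#5]~[#5]'),
    (274, '[#5]~[#6]'),
    (275, '[#5]~[#7]'),
    (276, '[#5]~[#8]'),
    (277, '[#5]~[F]'),
    (278, '[#5]~[#14]'),
    (279, '[#5]~[#15]'),
    (280, '[#5]~[#16]'),
    (281, '[#5]~[Cl]'),
    (282, '[#5]~[Br]'),
    (283, '[#6&!H0]'),
    (284, '[#6]~[#6]'),
    (285, '[#6]~[#7]'),
    (286, '[#6]~[#8]'),
    (287, '[#6]~[F]'),
    (288, '[#6]~[Na]'),
    (289, '[#6]~[Mg]'),
    (290, '[#6]~[Al]'),
    (291, '[#6]~[#14]'),
    (292, '[#6]~[#15]'),
    (293, '[#6]~[#16]'),
    (294, '[#6]~[Cl]'),
    (295, '[#6]~[#33]'),
    (296, '[#6]~[#34]'),
    (297, '[#6]~[Br]'),
    (298, '[#6]~[I]'),
    (299, '[#7&!H0]'),
    (300, '[#7]~[#7]'),
    (301, '[#7]~[#8]'),
    (302, '[#7]~[F]'),
    (303, '[#7]~[#14]'),
    (304, '[#7]~[#15]'),
    (305, '[#7]~[#16]'),
    (306, '[#7]~[Cl]'),
    (307, '[#7]~[Br]'),
    (308, '[#8&!H0]'),
    (309, '[#8]~[#8]'),
    (310, '[#8]~[Mg]'),
    (311, '[#8]~[Na]'),
    (312, '[#8]~[Al]'),
    (313, '[#8]~[#14]'),
    (314, '[#8]~[#15]'),
    (315, '[#8]~[K]'),
    (316, '[F]~[#15]'),
    (317, '[F]~[#16]'),
    (318, '[Al&!H0]'),
    (319, '[Al]~[Cl]'),
    (320, '[#14&!H0]'),
    (321, '[#14]~[#14]'),
    (322, '[#14]~[Cl]'),
    (323, '[#15&!H0]'),
    (324, '[#15]~[#15]'),
    (325, '[#33&!H0]'),
    (326, '[#33]~[#33]'),
    (327, '[#6](~Br)(~[#6])'),
    (328, '[#6](~Br)(~[#6])(~[#6])'),
    (329, '[#6&!H0]~[Br]'),
    (330, '[#6](~[Br])(:[c])'),
    (331, '[#6](~[Br])(:[n])'),
    (332, '[#6](~[#6])(~[#6])'),
    (333, '[#6](~[#6])(~[#6])(~[#6])'),
    (334, '[#6](~[#6])(~[#6])(~[#6])(~[#6])'),
    (335, '[#6H1](~[#6])(~[#6])(~[#6])'),
    (336, '[#6](~[#6])(~[#6])(~[#6])(~[#7])'),
    (337, '[#6](~[#6])(~[#6])(~[#6])(~[#8])'),
    (338, '[#6H1](~[#6])(~[#6])(~[#7])'),
    (339, '[#6H1](~[#6])(~[#6])(~[#8])'),
    (340, '[#6](~[#6])(~[#6])(~[#7])'),
    (341, '[#6](~[#6])(~[#6])(~[#8])'),
    (342, '[#6](~[#6])(~[Cl])'),
    (343, '[#6&!H0](~[#6])(~[Cl])'),
    (344, '[#6H,#6H2,#6H3,#6H4]~[#6]'),
    (345, '[#6&!H0](~[#6])(~[#7])'),
    (346, '[#6&!H0](~[#6])(~[#8])'),
    (347, '[#6H1](~[#6])(~[#8])(~[#8])'),
    (348, '[#6&!H0](~[#6])(~[#15])'),
    (349, '[#6&!H0](~[#6])(~[#16])'),
    (350, '[#6](~[#6])(~[I])'),
    (351, '[#6](~[#6])(~[#7])'),
    (352, '[#6](~[#6])(~[#8])'),
    (353, '[#6](~[#6])(~[#16])'),
    (354, '[#6](~[#6])(~[#14])'),
    (355, '[#6](~[#6])(:c)'),
    (356, '[#6](~[#6])(:c)(:c)'),
    (357, '[#6](~[#6])(:c)(:n)'),
    (358, '[#6](~[#6])(:n)'),
    (359, '[#6](~[#6])(:n)(:n)'),
    (360, '[#6](~[Cl])(~[Cl])'),
    (361, '[#6&!H0](~[Cl])'),
    (362, '[#6](~[Cl])(:c)'),
    (363, '[#6](~[F])(~[F])'),
    (364, '[#6](~[F])(:c)'),
    (365, '[#6&!H0](~[#7])'),
    (366, '[#6&!H0](~[#8])'),
    (367, '[#6&!H0](~[#8])(~[#8])'),
    (368, '[#6&!H0](~[#16])'),
    (369, '[#6&!H0](~[#14])'),
    (370, '[#6&!H0]:c'),
    (371, '[#6&!H0](:c)(:c)'),
    (372, '[#6&!H0](:c)(:n)'),
    (373, '[#6&!H0](:n)'),
    (374, '[#6H3]'),
    (375, '[#6](~[#7])(~[#7])'),
    (376, '[#6](~[#7])(:c)'),
    (377, '[#6](~[#7])(:c)(:c)'),
    (378, '[#6](~[#7])(:c)(:n)'),
    (379, '[#6](~[#7])(:n)'),
    (380, '[#6](~[#8])(~[#8])'),
    (381, '[#6](~[#8])(:c)'),
    (382, '[#6](~[#8])(:c)(:c)'),
    (383, '[#6](~[#16])(:c)'),
    (384, '[#6](:c)(:c)'),
    (385, '[#6](:c)(:c)(:c)'),
    (386, '[#6](:c)(:c)(:n)'),
    (387, '[#6](:c)(:n)'),
    (388, '[#6](:c)(:n)(:n)'),
    (389, '[#6](:n)(:n)'),
    (390, '[#7](~[#6])(~[#6])'),
    (391, '[#7](~[#6])(~[#6])(~[#6])'),
    (392, '[#7&!H0](~[#6])(~[#6])'),
    (393, '[#7&!H0](~[#6])'),
    (394, '[#7&!H0](~[#6])(~[#7])'),
    (395, '[#7](~[#6])(~[#8])'),
    (396, '[#7](~[#6])(:c)'),
    (397, '[#7](~[#6])(:c)(:c)'),
    (398, '[#7&!H0](~[#7])'),
    (399, '[#7&!H0](:c)'),
    (400, '[#7&!H0](:c)(:c)'),
    (401, '[#7](~[#8])(~[#8])'),
    (402, '[#7](~[#8])(:o)'),
    (403, '[#7](:c)(:c)'),
    (404, '[#7](:c)(:c)(:c)'),
    (405, '[#8](~[#6])(~[#6])'),
    (406, '[#8&!H0](~[#6])'),
    (407, '[#8](~[#6])(~[#15])'),
    (408, '[#8&!H0](~[#16])'),
    (409, '[#8](:c)(:c)'),
    (410, '[#15](~[#6])(~[#6])'),
    (411, '[#15](~[#8])(~[#8])'),
    (412, '[#16](~[#6])(~[#6])'),
    (413, '[#16&!H0](~[#6])'),
    (414, '[#16](~[#6])(~[#8])'),
    (415, '[#14](~[#6])(~[#6])'),
    (416, '[#6]=,:[#6]'),
    (417, '[#6]#[#6]'),
    (418, '[#6]=,:[#7]'),
    (419, '[#6]#[#7]'),
    (420, '[#6]=,:[#8]'),
    (421, '[#6]=,:[#16]'),
    (422, '[#7]=,:[#7]'),
    (423, '[#7]=,:[#8]'),
    (424, '[#7]=,:[#15]'),
    (425, '[#15]=,:[#8]'),
    (426, '[#15]=,:[#15]'),
    (427, '[#6](#[#6])(-,:[#6])'),
    (428, '[#6&!H0](#[#6])'),
    (429, '[#6](#[#7])(-,:[#6])'),
    (430, '[#6](-,:[#6])(-,:[#6])(=,:[#6])'),
    (431, '[#6](-,:[#6])(-,:[#6])(=,:[#7])'),
    (432, '[#6](-,:[#6])(-,:[#6])(=,:[#8])'),
    (433, '[#6](-,:[#6])([Cl])(=,:[#8])'),
    (434, '[#6&!H0](-,:[#6])(=,:[#6])'),
    (435, '[#6&!H0](-,:[#6])(=,:[#7])'),
    (436, '[#6&!H0](-,:[#6])(=,:[#8])'),
    (437, '[#6](-,:[#6])(-,:[#7])(=,:[#6])'),
    (438, '[#6](-,:[#6])(-,:[#7])(=,:[#7])'),
    (439, '[#6](-,:[#6])(-,:[#7])(=,:[#8])'),
    (440, '[#6](-,:[#6])(-,:[#8])(=,:[#8])'),
    (441, '[#6](-,:[#6])(=,:[#6])'),
    (442, '[#6](-,:[#6])(=,:[#7])'),
    (443, '[#6](-,:[#6])(=,:[#8])'),
    (444, '[#6]([Cl])(=,:[#8])'),
    (445, '[#6&!H0](-,:[#7])(=,:[#6])'),
    (446, '[#6&!H0](=,:[#6])'),
    (447, '[#6&!H0](=,:[#7])'),
    (448, '[#6&!H0](=,:[#8])'),
    (449, '[#6](-,:[#7])(=,:[#6])'),
    (450, '[#6](-,:[#7])(=,:[#7])'),
    (451, '[#6](-,:[#7])(=,:[#8])'),
    (452, '[#6](-,:[#8])(=,:[#8])'),
    (453, '[#7](-,:[#6])(=,:[#6])'),
    (454, '[#7](-,:[#6])(=,:[#8])'),
    (455, '[#7](-,:[#8])(=,:[#8])'),
    (456, '[#15](-,:[#8])(=,:[#8])'),
    (457, '[#16](-,:[#6])(=,:[#8])'),
    (458, '[#16](-,:[#8])(=,:[#8])'),
    (459, '[#16](=,:[#8])(=,:[#8])'),
    (460, '[#6]-,:[#6]-,:[#6]#[#6]'),
    (461, '[#8]-,:[#6]-,:[#6]=,:[#7]'),
    (462, '[#8]-,:[#6]-,:[#6]=,:[#8]'),
    (463, '[#7]:[#6]-,:[#16&!H0]'),
    (464, '[#7]-,:[#6]-,:[#6]=,:[#6]'),
    (465, '[#8]=,:[#16]-,:[#6]-,:[#6]'),
    (466, '[#7]#[#6]-,:[#6]=,:[#6]'),
    (467, '[#6]=,:[#7]-,:[#7]-,:[#6]'),
    (468, '[#8]=,:[#16]-,:[#6]-,:[#7]'),
    (469, '[#16]-,:[#16]-,:[#6]:[#6]'),
    (470, '[#6]:[#6]-,:[#6]=,:[#6]'),
    (471, '[#16]:[#6]:[#6]:[#6]'),
    (472, '[#6]:[#7]:[#6]-,:[#6]'),
    (473, '[#16]-,:[#6]:[#7]:[#6]'),
    (474, '[#16]:[#6]:[#6]:[#7]'),
    (475, '[#16]-,:[#6]=,:[#7]-,:[#6]'),
    (476, '[#6]-,:[#8]-,:[#6]=,:[#6]'),
    (477, '[#7]-,:[#7]-,:[#6]:[#6]'),
    (478, '[#16]-,:[#6]=,:[#7&!H0]'),
    (479, '[#16]-,:[#6]-,:[#16]-,:[#6]'),
    (480, '[#6]:[#16]:[#6]-,:[#6]'),
    (481, '[#8]-,:[#16]-,:[#6]:[#6]'),
    (482, '[#6]:[#7]-,:[#6]:[#6]'),
    (483, '[#7]-,:[#16]-,:[#6]:[#6]'),
    (484, '[#7]-,:[#6]:[#7]:[#6]'),
    (485, '[#7]:[#6]:[#6]:[#7]'),
    (486, '[#7]-,:[#6]:[#7]:[#7]'),
    (487, '[#7]-,:[#6]=,:[#7]-,:[#6]'),
    (488, '[#7]-,:[#6]=,:[#7&!H0]'),
    (489, '[#7]-,:[#6]-,:[#16]-,:[#6]'),
    (490, '[#6]-,:[#6]-,:[#6]=,:[#6]'),
    (491, '[#6]-,:[#7]:[#6&!H0]'),
    (492, '[#7]-,:[#6]:[#8]:[#6]'),
    (493, '[#8]=,:[#6]-,:[#6]:[#6]'),
    (494, '[#8]=,:[#6]-,:[#6]:[#7]'),
    (495, '[#6]-,:[#7]-,:[#6]:[#6]'),
    (496, '[#7]:[#7]-,:[#6&!H0]'),
    (497, '[#8]-,:[#6]:[#6]:[#7]'),
    (498, '[#8]-,:[#6]=,:[#6]-,:[#6]'),
    (499, '[#7]-,:[#6]:[#6]:[#7]'),
    (500, '[#6]-,:[#16]-,:[#6]:[#6]'),
    (501, '[Cl]-,:[#6]:[#6]-,:[#6]'),
    (502, '[#7]-,:[#6]=,:[#6&!H0]'),
    (503, '[Cl]-,:[#6]:[#6&!H0]'),
    (504, '[#7]:[#6]:[#7]-,:[#6]'),
    (505, '[Cl]-,:[#6]:[#6]-,:[#8]'),
    (506, '[#6]-,:[#6]:[#7]:[#6]'),
    (507, '[#6]-,:[#6]-,:[#16]-,:[#6]'),
    (508, '[#16]=,:[#6]-,:[#7]-,:[#6]'),
    (509, '[Br]-,:[#6]:[#6]-,:[#6]'),
    (510, '[#7&!H0]-,:[#7&!H0]'),
    (511, '[#16]=,:[#6]-,:[#7&!H0]'),
    (512, '[#6]-,:[#33]-[#8&!H0]'),
    (513, '[#16]:[#6]:[#6&!H0]'),
    (514, '[#8]-,:[#7]-,:[#6]-,:[#6]'),
    (515, '[#7]-,:[#7]-,:[#6]-,:[#6]'),
    (516, '[#6H,#6H2,#6H3]=,:[#6H,#6H2,#6H3]'),
    (517, '[#7]-,:[#7]-,:[#6]-,:[#7]'),
    (518, '[#8]=,:[#6]-,:[#7]-,:[#7]'),
    (519, '[#7]=,:[#6]-,:[#7]-,:[#6]'),
    (520, '[#6]=,:[#6]-,:[#6]:[#6]'),
    (521, '[#6]:[#7]-,:[#6&!H0]'),
    (522, '[#6]-,:[#7]-,:[#7&!H0]'),
    (523, '[#7]:[#6]:[#6]-,:[#6]'),
    (524, '[#6]-,:[#6]=,:[#6]-,:[#6]'),
    (525, '[#33]-,:[#6]:[#6&!H0]'),
    (526, '[Cl]-,:[#6]:[#6]-,:[Cl]'),
    (527, '[#6]:[#6]:[#7&!H0]'),
    (528, '[#7&!H0]-,:[#6&!H0]'),
    (529, '[Cl]-,:[#6]-,:[#6]-,:[Cl]'),
    (530, '[#7]:[#6]-,:[#6]:[#6]'),
    (531, '[#16]-,:[#6]:[#6]-,:[#6]'),
    (532, '[#16]-,:[#6]:[#6&!H0]'),
    (533, '[#16]-,:[#6]:[#6]-,:[#7]'),
    (534, '[#16]-,:[#6]:[#6]-,:[#8]'),
    (535, '[#8]=,:[#6]-,:[#6]-,:[#6]'),
    (536, '[#8]=,:[#6]-,:[#6]-,:[#7]'),
    (537, '[#8]=,:[#6]-,:[#6]-,:[#8]'),
    (538, '[#7]=,:[#6]-,:[#6]-,:[#6]'),
    (539, '[#7]=,:[#6]-,:[#6&!H0]'),
    (540, '[#6]-,:[#7]-,:[#6&!H0]'),
    (541, '[#8]-,:[#6]:[#6]-,:[#6]'),
    (542, '[#8]-,:[#6]:[#6&!H0]'),
    (543, '[#8]-,:[#6]:[#6]-,:[#7]'),
    (544, '[#8]-,:[#6]:[#6]-,:[#8]'),
    (545, '[#7]-,:[#6]:[#6]-,:[#6]'),
    (546, '[#7]-,:[#6]:[#6&!H0]'),
    (547, '[#7]-,:[#6]:[#6]-,:[#7]'),
    (548, '[#8]-,:[#6]-,:[#6]:[#6]'),
    (549, '[#7]-,:[#6]-,:[#6]:[#6]'),
    (550, '[Cl]-,:[#6]-,:[#6]-,:[#6]'),
    (551, '[Cl]-,:[#6]-,:[#6]-,:[#8]'),
    (552, '[#6]:[#6]-,:[#6]:[#6]'),
    (553, '[#8]=,:[#6]-,:[#6]=,:[#6]'),
    (554, '[Br]-,:[#6]-,:[#6]-,:[#6]'),
    (555, '[#7]=,:[#6]-,:[#6]=,:[#6]'),
    (556, '[#6]=,:[#6]-,:[#6]-,:[#6]'),
    (557, '[#7]:[#6]-,:[#8&!H0]'),
    (558, '[#8]=,:[#7]-,:c:c'),
    (559, '[#8]-,:[#6]-,:[#7&!H0]'),
    (560, '[#7]-,:[#6]-,:[#7]-,:[#6]'),
    (561, '[Cl]-,:[#6]-,:[#6]=,:[#8]'),
    (562, '[Br]-,:[#6]-,:[#6]=,:[#8]'),
    (563, '[#8]-,:[#6]-,:[#8]-,:[#6]'),
    (564, '[#6]=,:[#6]-,:[#6]=,:[#6]'),
    (565, '[#6]:[#6]-,:[#8]-,:[#6]'),
    (566, '[#8]-,:[#6]-,:[#6]-,:[#7]'),
    (567, '[#8]-,:[#6]-,:[#6]-,:[#8]'),
    (568, 'N#[#6]-,:[#6]-,:[#6]'),
    (569, '[#7]-,:[#6]-,:[#6]-,:[#7]'),
    (570, '[#6]:[#6]-,:[#6]-,:[#6]'),
    (571, '[#6&!H0]-,:[#8&!H0]'),
    (572, 'n:c:n:c'),
    (573, '[#8]-,:[#6]-,:[#6]=,:[#6]'),
    (574, '[#8]-,:[#6]-,:[#6]:[#6]-,:[#6]'),
    (575, '[#8]-,:[#6]-,:[#6]:[#6]-,:[#8]'),
    (576, '[#7]=,:[#6]-,:[#6]:[#6&!H0]'),
    (577, 'c:c-,:[#7]-,:c:c'),
    (578, '[#6]-,:[#6]:[#6]-,:c:c'),
    (579, '[#8]=,:[#6]-,:[#6]-,:[#6]-,:[#6]'),
    (580, '[#8]=,:[#6]-,:[#6]-,:[#6]-,:[#7]'),
    (581, '[#8]=,:[#6]-,:[#6]-,:[#6]-,:[#8]'),
    (582, '[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6]'),
    (583, '[Cl]-,:[#6]:[#6]-,:[#8]-,:[#6]'),
    (584, 'c:c-,:[#6]=,:[#6]-,:[#6]'),
    (585, '[#6]-,:[#6]:[#6]-,:[#7]-,:[#6]'),
    (586, '[#6]-,:[#16]-,:[#6]-,:[#6]-,:[#6]'),
    (587, '[#7]-,:[#6]:[#6]-,:[#8&!H0]'),
    (588, '[#8]=,:[#6]-,:[#6]-,:[#6]=,:[#8]'),
    (589, '[#6]-,:[#6]:[#6]-,:[#8]-,:[#6]'),
    (590, '[#6]-,:[#6]:[#6]-,:[#8&!H0]'),
    (591, '[Cl]-,:[#6]-,:[#6]-,:[#6]-,:[#6]'),
    (592, '[#7]-,:[#6]-,:[#6]-,:[#6]-,:[#6]'),
    (593, '[#7]-,:[#6]-,:[#6]-,:[#6]-,:[#7]'),
    (594, '[#6]-,:[#8]-,:[#6]-,:[#6]=,:[#6]'),
    (595, 'c:c-,:[#6]-,:[#6]-,:[#6]'),
    (596, '[#7]=,:[#6]-,:[#7]-,:[#6]-,:[#6]'),
    (597, '[#8]=,:[#6]-,:[#6]-,:c:c'),
    (598, '[Cl]-,:[#6]:[#6]:[#6]-,:[#6]'),
    (599, '[#6H,#6H2,#6H3]-,:[#6]=,:[#6H,#6H2,#6H3]'),
    (600, '[#7]-,:[#6]:[#6]:[#6]-,:[#6]'),
    (601, '[#7]-,:[#6]:[#6]:[#6]-,:[#7]'),
    (602, '[#8]=,:[#6]-,:[#6]-,:[#7]-,:[#6]'),
    (603, '[#6]-,:c:c:[#6]-,:[#6]'),
    (604, '[#6]-,:[#8]-,:[#6]-,:[#6]:c'),
    (605, '[#8]=,:[#6]-,:[#6]-,:[#8]-,:[#6]'),
    (606, '[#8]-,:[#6]:[#6]-,:[#6]-,:[#6]'),
    (607, '[#7]-,:[#6]-,:[#6]-,:[#6]:c'),
    (608, '[#6]-,:[#6]-,:[#6]-,:[#6]:c'),
    (609, '[Cl]-,:[#6]-,:[#6]-,:[#7]-,:[#6]'),
    (610, '[#6]-,:[#8]-,:[#6]-,:[#8]-,:[#6]'),
    (611, '[#7]-,:[#6]-,:[#6]-,:[#7]-,:[#6]'),
    (612, '[#7]-,:[#6]-,:[#8]-,:[#6]-,:[#6]'),
    (613, '[#6]-,:[#7]-,:[#6]-,:[#6]-,:[#6]'),
    (614, '[#6]-,:[#6]-,:[#8]-,:[#6]-,:[#6]'),
    (615, '[#7]-,:[#6]-,:[#6]-,:[#8]-,:[#6]'),
    (616, 'c:c:n:n:c'),
    (617, '[#6]-,:[#6]-,:[#6]-,:[#8&!H0]'),
    (618, 'c:[#6]-,:[#6]-,:[#6]:c'),
    (619, '[#8]-,:[#6]-,:[#6]=,:[#6]-,:[#6]'),
    (620, 'c:c-,:[#8]-,:[#6]-,:[#6]'),
    (621, '[#7]-,:[#6]:c:c:n'),
    (622, '[#8]=,:[#6]-,:[#8]-,:[#6]:c'),
    (623, '[#8]=,:[#6]-,:[#6]:[#6]-,:[#6]'),
    (624, '[#8]=,:[#6]-,:[#6]:[#6]-,:[#7]'),
    (625, '[#8]=,:[#6]-,:[#6]:[#6]-,:[#8]'),
    (626, '[#6]-,:[#8]-,:[#6]:[#6]-,:[#6]'),
    (627, '[#8]=,:[#33]-,:[#6]:c:c'),
    (628, '[#6]-,:[#7]-,:[#6]-,:[#6]:c'),
    (629, '[#16]-,:[#6]:c:c-,:[#7]'),
    (630, '[#8]-,:[#6]:[#6]-,:[#8]-,:[#6]'),
    (631, '[#8]-,:[#6]:[#6]-,:[#8&!H0]'),
    (632, '[#6]-,:[#6]-,:[#8]-,:[#6]:c'),
    (633, '[#7]-,:[#6]-,:[#6]:[#6]-,:[#6]'),
    (634, '[#6]-,:[#6]-,:[#6]:[#6]-,:[#6]'),
    (635, '[#7]-,:[#7]-,:[#6]-,:[#7&!H0]'),
    (636, '[#6]-,:[#7]-,:[#6]-,:[#7]-,:[#6]'),
    (637, '[#8]-,:[#6]-,:[#6]-,:[#6]-,:[#6]'),
    (638, '[#8]-,:[#6]-,:[#6]-,:[#6]-,:[#7]'),
    (639, '[#8]-,:[#6]-,:[#6]-,:[#6]-,:[#8]'),
    (640, '[#6]=,:[#6]-,:[#6]-,:[#6]-,:[#6]'),
    (641, '[#8]-,:[#6]-,:[#6]-,:[#6]=,:[#6]'),
    (642, '[#8]-,:[#6]-,:[#6]-,:[#6]=,:[#8]'),
    (643, '[#6&!H0]-,:[#6]-,:[#7&!H0]'),
    (644, '[#6]-,:[#6]=,:[#7]-,:[#7]-,:[#6]'),
    (645, '[#8]=,:[#6]-,:[#7]-,:[#6]-,:[#6]'),
    (646, '[#8]=,:[#6]-,:[#7]-,:[#6&!H0]'),
    (647, '[#8]=,:[#6]-,:[#7]-,:[#6]-,:[#7]'),
    (648, '[#8]=,:[#7]-,:[#6]:[#6]-,:[#7]'),
    (649, '[#8]=,:[#7]-,:c:c-,:[#8]'),
    (650, '[#8]=,:[#6]-,:[#7]-,:[#6]=,:[#8]'),
    (651, '[#8]-,:[#6]:[#6]:[#6]-,:[#6]'),
    (652, '[#8]-,:[#6]:[#6]:[#6]-,:[#7]'),
    (653, '[#8]-,:[#6]:[#6]:[#6]-,:[#8]'),
    (654, '[#7]-,:[#6]-,:[#7]-,:[#6]-,:[#6]'),
    (655, '[#8]-,:[#6]-,:[#6]-,:[#6]:c'),
    (656, '[#6]-,:[#6]-,:[#7]-,:[#6]-,:[#6]'),
    (657, '[#6]-,:[#7]-,:[#6]:[#6]-,:[#6]'),
    (658, '[#6]-,:[#6]-,:[#16]-,:[#6]-,:[#6]'),
    (659, '[#8]-,:[#6]-,:[#6]-,:[#7]-,:[#6]'),
    (660, '[#6]-,:[#6]=,:[#6]-,:[#6]-,:[#6]'),
    (661, '[#8]-,:[#6]-,:[#8]-,:[#6]-,:[#6]'),
    (662, '[#8]-,:[#6]-,:[#6]-,:[#8]-,:[#6]'),
    (663, '[#8]-,:[#6]-,:[#6]-,:[#8&!H0]'),
    (664, '[#6]-,:[#6]=,:[#6]-,:[#6]=,:[#6]'),
    (665, '[#7]-,:[#6]:[#6]-,:[#6]-,:[#6]'),
    (666, '[#6]=,:[#6]-,:[#6]-,:[#8]-,:[#6]'),
    (667, '[#6]=,:[#6]-,:[#6]-,:[#8&!H0]'),
    (668, '[#6]-,:[#6]:[#6]-,:[#6]-,:[#6]'),
    (669, '[Cl]-,:[#6]:[#6]-,:[#6]=,:[#8]'),
    (670, '[Br]-,:[#6]:c:c-,:[#6]'),
    (671, '[#8]=,:[#6]-,:[#6]=,:[#6]-,:[#6]'),
    (672, '[#8]=,:[#6]-,:[#6]=,:[#6&!H0]'),
    (673, '[#8]=,:[#6]-,:[#6]=,:[#6]-,:[#7]'),
    (674, '[#7]-,:[#6]-,:[#7]-,:[#6]:c'),
    (675, '[Br]-,:[#6]-,:[#6]-,:[#6]:c'),
    (676, '[#7]#[#6]-,:[#6]-,:[#6]-,:[#6]'),
    (677, '[#6]-,:[#6]=,:[#6]-,:[#6]:c'),
    (678, '[#6]-,:[#6]-,:[#6]=,:[#6]-,:[#6]'),
    (679, '[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6]'),
    (680, '[#8]-,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6]'),
    (681, '[#8]-,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#8]'),
    (682, '[#8]-,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#7]'),
    (683, '[#7]-,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6]'),
    (684, '[#8]=,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6]'),
    (685, '[#8]=,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#7]'),
    (686, '[#8]=,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#8]'),
    (687, '[#8]=,:[#6]-,:[#6]-,:[#6]-,:[#6]=,:[#8]'),
    (688, '[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6]'),
    (689, '[#8]-,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6]'),
    (690, '[#8]-,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#8]'),
    (691, '[#8]-,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#7]'),
    (692, '[#8]=,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6]'),
    (693, '[#8]=,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#8]'),
    (694, '[#8]=,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6]=,:[#8]'),
    (695, '[#8]=,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#7]'),
    (696, '[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6]'),
    (697, '[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6](-,:[#6])-,:[#6]'),
    (698, '[#8]-,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6]'),
    (699, '[#8]-,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6](-,:[#6])-,:[#6]'),
    (700, '[#8]-,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#8]-,:[#6]'),
    (701, '[#8]-,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6](-,:[#8])-,:[#6]'),
    (702, '[#8]-,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#7]-,:[#6]'),
    (703, '[#8]-,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6](-,:[#7])-,:[#6]'),
    (704, '[#8]=,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6]'),
    (705, '[#8]=,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6](-,:[#8])-,:[#6]'),
    (706, '[#8]=,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6](=,:[#8])-,:[#6]'),
    (707, '[#8]=,:[#6]-,:[#6]-,:[#6]-,:[#6]-,:[#6](-,:[#7])-,:[#6]'),
    (708, '[#6]-,:[#6](-,:[#6])-,:[#6]-,:[#6]'),
    (709, '[#6]-,:[#6](-,:[#6])-,:[#6]-,:[#6]-,:[#6]'),
    (710, '[#6]-,:[#6]-,:[#6](-,:[#6])-,:[#6]-,:[#6]'),
    (711, '[#6]-,:[#6](-,:[#6])(-,:[#6])-,:[#6]-,:[#6]'),
    (712, '[#6]-,:[#6](-,:[#6])-,:[#6](-,:[#6])-,:[#6]'),
    (713, '[#6]c1ccc([#6])cc1'),
    (714, '[#6]c1ccc([#8])cc1'),
    (715, '[#6]c1ccc([#16])cc1'),
    (716, '[#6]c1ccc([#7])cc1'),
    (717, '[#6]c1ccc(Cl)cc1'),
    (718, '[#6]c1ccc(Br)cc1'),
    (719, '[#8]c1ccc([#8])cc1'),
    (720, '[#8]c1ccc([#16])cc1'),
    (721, '[#8]c1ccc([#7])cc1'),
    (722, '[#8]c1ccc(Cl)cc1'),
    (723, '[#8]c1ccc(Br)cc1'),
    (724, '[#16]c1ccc([#16])cc1'),
    (725, '[#16]c1ccc([#7])cc1'),
    (726, '[#16]c1ccc(Cl)cc1'),
    (727, '[#16]c1ccc(Br)cc1'),
    (728, '[#7]c1ccc([#7])cc1'),
    (729, '[#7]c1ccc(Cl)cc1'),
    (730, '[#7]c1ccc(Br)cc1'),
    (731, 'Clc1ccc(Cl)cc1'),
    (732, 'Clc1ccc(Br)cc1'),
    (733, 'Brc1ccc(Br)cc1'),
    (734, '[#6]c1cc([#6])ccc1'),
    (735, '[#6]c1cc([#8])ccc1'),
    (736, '[#6]c1cc([#16])ccc1'),
    (737, '[#6]c1cc([#7])ccc1'),
    (738, '[#6]c1cc(Cl)ccc1'),
    (739, '[#6]c1cc(Br)ccc1'),
    (740, '[#8]c1cc([#8])ccc1'),
    (741, '[#8]c1cc([#16])ccc1'),
    (742, '[#8]c1cc([#7])ccc1'),
    (743, '[#8]c1cc(Cl)ccc1'),
    (744, '[#8]c1cc(Br)ccc1'),
    (745, '[#16]c1cc([#16])ccc1'),
    (746, '[#16]c1cc([#7])ccc1'),
    (747, '[#16]c1cc(Cl)ccc1'),
    (748, '[#16]c1cc(Br)ccc1'),
    (749, '[#7]c1cc([#7])ccc1'),
    (750, '[#7]c1cc(Cl)ccc1'),
    (751, '[#7]c1cc(Br)ccc1'),
    (752, 'Clc1cc(Cl)ccc1'),
    (753, 'Clc1cc(Br)ccc1'),
    (754, 'Brc1cc(Br)ccc1'),
    (755, '[#6]c1c([#6])cccc1'),
    (756, '[#6]c1c([#8])cccc1'),
    (757, '[#6]c1c([#16])cccc1'),
    (758, '[#6]c1c([#7])cccc1'),
    (759, '[#6]c1c(Cl)cccc1'),
    (760, '[#6]c1c(Br)cccc1'),
    (761, '[#8]c1c([#8])cccc1'),
    (762, '[#8]c1c([#16])cccc1'),
    (763, '[#8]c1c([#7])cccc1'),
    (764, '[#8]c1c(Cl)cccc1'),
    (765, '[#8]c1c(Br)cccc1'),
    (766, '[#16]c1c([#16])cccc1'),
    (767, '[#16]c1c([#7])cccc1'),
    (768, '[#16]c1c(Cl)cccc1'),
    (769, '[#16]c1c(Br)cccc1'),
    (770, '[#7]c1c([#7])cccc1'),
    (771, '[#7]c1c(Cl)cccc1'),
    (772, '[#7]c1c(Br)cccc1'),
    (773, 'Clc1c(Cl)cccc1'),
    (774, 'Clc1c(Br)cccc1'),
    (775, 'Brc1c(Br)cccc1'),
    (776, '[#6][#6]1[#6][#6][#6]([#6])[#6][#6]1'),
    (777, '[#6][#6]1[#6][#6][#6]([#8])[#6][#6]1'),
    (778, '[#6][#6]1[#6][#6][#6]([#16])[#6][#6]1'),
    (779, '[#6][#6]1[#6][#6][#6]([#7])[#6][#6]1'),
    (780, '[#6][#6]1[#6][#6][#6](Cl)[#6][#6]1'),
    (781, '[#6][#6]1[#6][#6][#6](Br)[#6][#6]1'),
    (782, '[#8][#6]1[#6][#6][#6]([#8])[#6][#6]1'),
    (783, '[#8][#6]1[#6][#6][#6]([#16])[#6][#6]1'),
    (784, '[#8][#6]1[#6][#6][#6]([#7])[#6][#6]1'),
    (785, '[#8][#6]1[#6][#6][#6](Cl)[#6][#6]1'),
    (786, '[#8][#6]1[#6][#6][#6](Br)[#6][#6]1'),
    (787, '[#16][#6]1[#6][#6][#6]([#16])[#6][#6]1'),
    (788, '[#16][#6]1[#6][#6][#6]([#7])[#6][#6]1'),
    (789, '[#16][#6]1[#6][#6][#6](Cl)[#6][#6]1'),
    (790, '[#16][#6]1[#6][#6][#6](Br)[#6][#6]1'),
    (791, '[#7][#6]1[#6][#6][#6]([#7])[#6][#6]1'),
    (792, '[#7][#6]1[#6][#6][#6](Cl)[#6][#6]1'),
    (793, '[#7][#6]1[#6][#6][#6](Br)[#6][#6]1'),
    (794, 'Cl[#6]1[#6][#6][#6](Cl)[#6][#6]1'),
    (795, 'Cl[#6]1[#6][#6][#6](Br)[#6][#6]1'),
    (796, 'Br[#6]1[#6][#6][#6](Br)[#6][#6]1'),
    (797, '[#6][#6]1[#6][#6]([#6])[#6][#6][#6]1'),
    (798, '[#6][#6]1[#6][#6]([#8])[#6][#6][#6]1'),
    (799, '[#6][#6]1[#6][#6]([#16])[#6][#6][#6]1'),
    (800, '[#6][#6]1[#6][#6]([#7])[#6][#6][#6]1'),
    (801, '[#6][#6]1[#6][#6](Cl)[#6][#6][#6]1'),
    (802, '[#6][#6]1[#6][#6](Br)[#6][#6][#6]1'),
    (803, '[#8][#6]1[#6][#6]([#8])[#6][#6][#6]1'),
    (804, '[#8][#6]1[#6][#6]([#16])[#6][#6][#6]1'),
    (805, '[#8][#6]1[#6][#6]([#7])[#6][#6][#6]1'),
    (806, '[#8][#6]1[#6][#6](Cl)[#6][#6][#6]1'),
    (807, '[#8][#6]1[#6][#6](Br)[#6][#6][#6]1'),
    (808, '[#16][#6]1[#6][#6]([#16])[#6][#6][#6]1'),
    (809, '[#16][#6]1[#6][#6]([#7])[#6][#6][#6]1'),
    (810, '[#16][#6]1[#6][#6](Cl)[#6][#6][#6]1'),
    (811, '[#16][#6]1[#6][#6](Br)[#6][#6][#6]1'),
    (812, '[#7][#6]1[#6][#6]([#7])[#6][#6][#6]1'),
    (813, '[#7][#6]1[#6][#6](Cl)[#6][#6][#6]1'),
    (814, '[#7][#6]1[#6][#6](Br)[#6][#6][#6]1'),
    (815, 'Cl[#6]1[#6][#6](Cl)[#6][#6][#6]1'),
    (816, 'Cl[#6]1[#6][#6](Br)[#6][#6][#6]1'),
    (817, 'Br[#6]1[#6][#6](Br)[#6][#6][#6]1'),
    (818, '[#6][#6]1[#6]([#6])[#6][#6][#6][#6]1'),
    (819, '[#6][#6]1[#6]([#8])[#6][#6][#6][#6]1'),
    (820, '[#6][#6]1[#6]([#16])[#6][#6][#6][#6]1'),
    (821, '[#6][#6]1[#6]([#7])[#6][#6][#6][#6]1'),
    (822, '[#6][#6]1[#6](Cl)[#6][#6][#6][#6]1'),
    (823, '[#6][#6]1[#6](Br)[#6][#6][#6][#6]1'),
    (824, '[#8][#6]1[#6]([#8])[#6][#6][#6][#6]1'),
    (825, '[#8][#6]1[#6]([#16])[#6][#6][#6][#6]1'),
    (826, '[#8][#6]1[#6]([#7])[#6][#6][#6][#6]1'),
    (827, '[#8][#6]1[#6](Cl)[#6][#6][#6][#6]1'),
    (828, '[#8][#6]1[#6](Br)[#6][#6][#6][#6]1'),
    (829, '[#16][#6]1[#6]([#16])[#6][#6][#6][#6]1'),
    (830, '[#16][#6]1[#6]([#7])[#6][#6][#6][#6]1'),
    (831, '[#16][#6]1[#6](Cl)[#6][#6][#6][#6]1'),
    (832, '[#16][#6]1[#6](Br)[#6][#6][#6][#6]1'),
    (833, '[#7][#6]1[#6]([#7])[#6][#6][#6][#6]1'),
    (834, '[#7][#6]1[#6](Cl)[#6][#6][#6][#6]1'),
    (835, '[#7][#6]1[#6](Br)[#6][#6][#6][#6]1'),
    (836, 'Cl[#6]1[#6](Cl)[#6][#6][#6][#6]1'),
    (837, 'Cl[#6]1[#6](Br)[#6][#6][#6][#6]1'),
    (838, 'Br[#6]1[#6](Br)[#6][#6][#6][#6]1'),
    (839, '[#6][#6]1[#6][#6]([#6])[#6][#6]1'),
    (840, '[#6][#6]1[#6][#6]([#8])[#6][#6]1'),
    (841, '[#6][#6]1[#6][#6]([#16])[#6][#6]1'),
    (842, '[#6][#6]1[#6][#6]([#7])[#6][#6]1'),
    (843, '[#6][#6]1[#6][#6](Cl)[#6][#6]1'),
    (844, '[#6][#6]1[#6][#6](Br)[#6][#6]1'),
    (845, '[#8][#6]1[#6][#6]([#8])[#6][#6]1'),
    (846, '[#8][#6]1[#6][#6]([#16])[#6][#6]1'),
    (847, '[#8][#6]1[#6][#6]([#7])[#6][#6]1'),
    (848, '[#8][#6]1[#6][#6](Cl)[#6][#6]1'),
    (849, '[#8][#6]1[#6][#6](Br)[#6][#6]1'),
    (850, '[#16][#6]1[#6][#6]([#16])[#6][#6]1'),
    (851, '[#16][#6]1[#6][#6]([#7])[#6][#6]1'),
    (852, '[#16][#6]1[#6][#6](Cl)[#6][#6]1'),
    (853, '[#16][#6]1[#6][#6](Br)[#6][#6]1'),
    (854, '[#7][#6]1[#6][#6]([#7])[#6][#6]1'),
    (855, '[#7][#6]1[#6][#6](Cl)[#6][#6]1'),
    (856, '[#7][#6]1[#6][#6](Br)[#6][#6]1'),
    (857, 'Cl[#6]1[#6][#6](Cl)[#6][#6]1'),
    (858, 'Cl[#6]1[#6][#6](Br)[#6][#6]1'),
    (859, 'Br[#6]1[#6][#6](Br)[#6][#6]1'),
    (860, '[#6][#6]1[#6]([#6])[#6][#6][#6]1'),
    (861, '[#6][#6]1[#6]([#8])[#6][#6][#6]1'),
    (862, '[#6][#6]1[#6]([#16])[#6][#6][#6]1'),
    (863, '[#6][#6]1[#6]([#7])[#6][#6][#6]1'),
    (864, '[#6][#6]1[#6](Cl)[#6][#6][#6]1'),
    (865, '[#6][#6]1[#6](Br)[#6][#6][#6]1'),
    (866, '[#8][#6]1[#6]([#8])[#6][#6][#6]1'),
    (867, '[#8][#6]1[#6]([#16])[#6][#6][#6]1'),
    (868, '[#8][#6]1[#6]([#7])[#6][#6][#6]1'),
    (869, '[#8][#6]1[#6](Cl)[#6][#6][#6]1'),
    (870, '[#8][#6]1[#6](Br)[#6][#6][#6]1'),
    (871, '[#16][#6]1[#6]([#16])[#6][#6][#6]1'),
    (872, '[#16][#6]1[#6]([#7])[#6][#6][#6]1'),
    (873, '[#16][#6]1[#6](Cl)[#6][#6][#6]1'),
    (874, '[#16][#6]1[#6](Br)[#6][#6][#6]1'),
    (875, '[#7][#6]1[#6]([#7])[#6][#6][#6]1'),
    (876, '[#7][#6]1[#6](Cl)[#6][#6]1'),
    (877, '[#7][#6]1[#6](Br)[#6][#6][#6]1'),
    (878, 'Cl[#6]1[#6](Cl)[#6][#6][#6]1'),
    (879, 'Cl[#6]1[#6](Br)[#6][#6][#6]1'),
    (880, 'Br[#6]1[#6](Br)[#6][#6][#6]1'),
]
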